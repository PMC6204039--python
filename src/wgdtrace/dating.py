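"""Ks-sample summarisation and molecular dating.

Filtered syntelog Ks samples are summarised two ways: a Student-t 95%
confidence interval of the mean, and Gaussian kernel density estimation to
locate distribution modes ("peaks"). Peaks are matched against a packaged
table of literature Ks ranges for named paleopolyploidy events (gamma,
salicoid, tau, rho, T, ...), and Ks converts to absolute time through the
standard per-lineage clock T = Ks / (2 r), with r in synonymous
substitutions per site per year.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "KsSample",
    "CiResult",
    "KsPeak",
    "WgdReference",
    "PeakAssignment",
    "DatingResult",
    "mean_ci",
    "kde_peaks",
    "silverman_bandwidth",
    "match_wgd",
    "ks_to_time",
    "rate_from_calibration",
    "load_reference_table",
]


@dataclass(frozen=True)
class KsSample:
    """Retained Ks values for one species / block scope."""

    values: tuple[float, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("empty Ks sample")
        if any(v <= 0 for v in self.values):
            raise ValueError("Ks sample values must be positive")


@dataclass(frozen=True)
class CiResult:
    mean: float
    lower: float
    upper: float
    level: float
    n: int


@dataclass(frozen=True)
class KsPeak:
    mode: float
    density_at_mode: float
    bandwidth: float


@dataclass(frozen=True)
class WgdReference:
    """Literature Ks range of a named polyploidy event in one lineage."""

    event: str
    lineage: str
    ks_low: float
    ks_high: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.ks_low < self.ks_high:
            raise ValueError(f"{self.event}: require ks_low < ks_high")

    @property
    def midpoint(self) -> float:
        return (self.ks_low + self.ks_high) / 2.0


@dataclass(frozen=True)
class PeakAssignment:
    peak: KsPeak
    candidates: tuple[WgdReference, ...]  # ranked by |mode - range midpoint|

    @property
    def event(self) -> str | None:
        return self.candidates[0].event if self.candidates else None

    @property
    def novel(self) -> bool:
        return not self.candidates


@dataclass(frozen=True)
class DatingResult:
    time_years: float
    time_ci: tuple[float, float] | None
    rate_used: float

    @property
    def mya(self) -> float:
        return self.time_years / 1e6

    @property
    def mya_ci(self) -> tuple[float, float] | None:
        if self.time_ci is None:
            return None
        return (self.time_ci[0] / 1e6, self.time_ci[1] / 1e6)


def mean_ci(sample: KsSample, level: float = 0.95) -> CiResult:
    """Student-t confidence interval of the sample mean (n = 1 collapses to
    a zero-width interval with a warning)."""
    x = np.asarray(sample.values, dtype=float)
    n = x.size
    m = float(x.mean())
    if n == 1:
        import warnings

        warnings.warn("n = 1: zero-width confidence interval")
        return CiResult(mean=m, lower=m, upper=m, level=level, n=1)
    sd = float(x.std(ddof=1))
    half = stats.t.ppf(0.5 + level / 2.0, df=n - 1) * sd / np.sqrt(n)
    return CiResult(mean=m, lower=m - half, upper=m + half, level=level, n=n)


def silverman_bandwidth(values: Sequence[float]) -> float:
    """Silverman's rule-of-thumb bandwidth, as R's ``bw.nrd0``:
    0.9 min(sd, IQR/1.34) n^{-1/5} (with fallbacks for degenerate spread)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread == 0.0:
        spread = max(abs(float(x[0])), 1.0)  # degenerate sample: nominal scale
    return 0.9 * spread * n ** (-0.2)


def kde_peaks(sample: KsSample, bandwidth: str | float = "silverman",
              grid_step: float = 0.01, min_rel_density: float = 0.25) -> list[KsPeak]:
    """Gaussian-kernel density peaks of a Ks sample.

    Density is evaluated on a regular grid over [0, max + 3h]; peaks are the
    local maxima whose density reaches ``min_rel_density`` of the global
    maximum, sorted by density descending.
    """
    x = np.asarray(sample.values, dtype=float)
    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        if x.size < 2:
            raise ValueError("silverman bandwidth needs n >= 2")
        h = silverman_bandwidth(x)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("fixed bandwidth must be positive")
    grid = np.arange(0.0, x.max() + 3 * h + grid_step, grid_step)
    # Gaussian KDE evaluated directly at bandwidth h
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    peaks: list[KsPeak] = []
    gmax = float(dens.max())
    for i in range(len(grid)):
        left = dens[i - 1] if i > 0 else -np.inf
        right = dens[i + 1] if i + 1 < len(grid) else -np.inf
        if dens[i] > left and dens[i] >= right and dens[i] >= min_rel_density * gmax:
            peaks.append(KsPeak(mode=float(grid[i]), density_at_mode=float(dens[i]),
                                bandwidth=h))
    peaks.sort(key=lambda p: -p.density_at_mode)
    return peaks


def match_wgd(ci: CiResult | None, peaks: Sequence[KsPeak],
              refs: Sequence[WgdReference],
              scope: str | None = None) -> list[PeakAssignment]:
    """Assign density peaks to literature WGD events.

    A reference is a candidate for a peak when the mode falls inside its Ks
    range or the sample CI overlaps the range; candidates are ranked by
    distance of the mode from the range midpoint. Peaks with no candidate
    are reported as novel.
    """
    if scope is not None:
        refs = [r for r in refs if r.lineage == scope]
    out = []
    for peak in peaks:
        cands = []
        for ref in refs:
            in_range = ref.ks_low <= peak.mode <= ref.ks_high
            ci_overlap = (
                ci is not None and ci.lower <= ref.ks_high and ci.upper >= ref.ks_low
            )
            if in_range or ci_overlap:
                cands.append(ref)
        cands.sort(key=lambda r: (abs(peak.mode - r.midpoint), r.event))
        out.append(PeakAssignment(peak=peak, candidates=tuple(cands)))
    return out


def ks_to_time(ks: float | CiResult, rate: float) -> DatingResult:
    """T = Ks / (2 r); a CiResult maps its endpoints through the same
    formula."""
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if isinstance(ks, CiResult):
        t = ks.mean / (2.0 * rate)
        return DatingResult(
            time_years=t,
            time_ci=(ks.lower / (2.0 * rate), ks.upper / (2.0 * rate)),
            rate_used=rate,
        )
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    return DatingResult(time_years=ks / (2.0 * rate), time_ci=None, rate_used=rate)


def rate_from_calibration(ks: float, time_years: float) -> float:
    """r = Ks / (2 T): the exact inverse of :func:`ks_to_time`."""
    if time_years <= 0:
        raise ValueError("calibration time must be positive")
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    return ks / (2.0 * time_years)


def load_reference_table(path: str | Path | None = None) -> list[WgdReference]:
    """Load the WGD reference table (packaged literature ranges by default;
    a user CSV with the same columns may be supplied instead)."""
    if path is None:
        source = resources.files("wgdtrace.data").joinpath("wgd_reference.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    refs = []
    for row in csv.DictReader(text.splitlines()):
        refs.append(WgdReference(
            event=row["event"], lineage=row["lineage"],
            ks_low=float(row["ks_low"]), ks_high=float(row["ks_high"]),
            source=row.get("source", ""),
        ))
    return refs
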