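"""Independent brute-force oracles used to validate the fast implementations.

These are deliberately naive and share no code (or precomputed tables) with
the package: NG86 counts come from fresh per-codon neighbour enumeration and
recursive pathway walks, and best chains from exhaustive subset enumeration.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}
NUCS = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_brute(codons_a: list[str], codons_b: list[str]) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) by direct enumeration; gap/stop/ambiguous columns skipped."""
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if set(ca) - set(NUCS) or set(cb) - set(NUCS):
            continue
        if ca in STOPS or cb in STOPS:
            continue
        # pathway average, skipping routes through stops
        diffs = [i for i in range(3) if ca[i] != cb[i]]
        path_sd, path_nd, n_paths = 0.0, 0.0, 0
        for order in itertools.permutations(diffs):
            cur, sd, nd, ok = ca, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if nxt in STOPS:
                    ok = False
                    break
                if _aa(nxt) == _aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                path_sd += sd
                path_nd += nd
                n_paths += 1
        if diffs and n_paths == 0:
            continue  # no stop-free pathway: column skipped
        # site counts (averaged over the two codons)
        s_col = 0.0
        for codon in (ca, cb):
            for pos in range(3):
                syn = valid = 0
                for n in NUCS:
                    if n == codon[pos]:
                        continue
                    nb = codon[:pos] + n + codon[pos + 1:]
                    if nb in STOPS:
                        continue
                    valid += 1
                    if _aa(nb) == _aa(codon):
                        syn += 1
                if valid:
                    s_col += syn / valid
        S += s_col / 2.0
        N += 3.0 - s_col / 2.0
        if diffs:
            Sd += path_sd / n_paths
            Nd += path_nd / n_paths
    return S, N, Sd, Nd


def best_chain_brute(ranks: list[tuple[int, int]], sims: list[float],
                     max_gap: int, gap_penalty: float) -> float:
    """Best chain score over all anchor subsets and both orientations."""
    n = len(ranks)
    best = float("-inf")
    for mask in range(1, 1 << n):
        idx = [i for i in range(n) if mask >> i & 1]
        idx.sort(key=lambda i: ranks[i][0])
        for sign in (1, -1):
            ok = True
            score = sims[idx[0]]
            for prev, cur in zip(idx, idx[1:]):
                da = ranks[cur][0] - ranks[prev][0]
                db = sign * (ranks[cur][1] - ranks[prev][1])
                if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                    ok = False
                    break
                score += sims[cur] - gap_penalty * ((da - 1) + (db - 1))
            if ok and score > best:
                best = score
    return best
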