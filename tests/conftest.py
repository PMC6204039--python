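from __future__ import annotations

import pytest

from wgdtrace import simulate


@pytest.fixture(scope="session")
def benchmark_sim():
    """The two-WGD recovery scenario (ancient Ks 1.0, recent 0.3,
    retention 0.8, 200 families x 300 codons), simulated once per session."""
    cfg = simulate.two_wgd_benchmark(seed=11)
    truth = simulate.simulate_history(cfg)
    seqs = simulate.simulate_sequences(truth)
    return cfg, truth, seqs


@pytest.fixture(scope="session")
def control_sim():
    """WGD-free control (100 families, same species tree)."""
    cfg = simulate.wgd_free_control(seed=12)
    truth = simulate.simulate_history(cfg)
    seqs = simulate.simulate_sequences(truth)
    return cfg, truth, seqs
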