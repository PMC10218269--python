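from __future__ import annotations

import pytest

from neuromethyl import (SimulationConfig, estimate_nonconversion,
                         simulate_annotation, simulate_methylome)


@pytest.fixture(scope="session")
def cfg_small() -> SimulationConfig:
    """A compact genome: 1 chromosome, 150 kb, 30 genes, ~18k sites."""
    return SimulationConfig(seed=11, n_chrom=1, chrom_length=150_000, n_genes=30)


@pytest.fixture(scope="session")
def ann_small(cfg_small):
    return simulate_annotation(cfg_small)


@pytest.fixture(scope="session")
def neuron_pair(cfg_small, ann_small):
    """(invitro sample, invivo sample, nonconversion dict) on the small genome."""
    a, spike_a = simulate_methylome(cfg_small, ann_small, "invitro_neuron", "invitro")
    b, spike_b = simulate_methylome(cfg_small, ann_small, "invivo_neuron", "invivo")
    ncs = {"invitro": estimate_nonconversion(spike_a),
           "invivo": estimate_nonconversion(spike_b)}
    return a, b, ncs
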