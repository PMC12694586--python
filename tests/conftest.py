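"""Shared fixtures: small deterministic simulation scenarios.

All fixture data is generated at test time by the simulate module; nothing
is read from disk except what the tests themselves write to tmp paths.
"""

from __future__ import annotations

import pytest

from iceseq import SimConfig, make_ice, simulate_sample


@pytest.fixture(scope="session")
def small_ice():
    """A 400 bp element with the default terminal motifs."""
    return make_ice(SimConfig(seed=7, ice_length_bp=400))


@pytest.fixture(scope="session")
def sim_clean():
    """Error-free two-genome scenario: 3 planted sites, 20% off-target."""
    cfg = SimConfig(
        seed=11,
        n_genomes=2,
        contig_length_bp=60_000,
        insertions=((0, 2), (1, 1)),
        ice_length_bp=2_000,
        reads_per_junction=40,
        error_rate=0.0,
        offtarget_fraction=0.2,
    )
    return simulate_sample(cfg)


@pytest.fixture(scope="session")
def sim_noisy():
    """Same genome scale with substitution errors, for robustness checks."""
    cfg = SimConfig(
        seed=13,
        n_genomes=2,
        contig_length_bp=50_000,
        insertions=((0, 1), (1, 2)),
        ice_length_bp=2_000,
        reads_per_junction=30,
        error_rate=0.005,
        offtarget_fraction=0.2,
    )
    return simulate_sample(cfg)
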