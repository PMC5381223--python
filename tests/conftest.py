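"""Shared fixtures: small simulated datasets reused across test modules.

Everything is generated programmatically and seeded, so the suite needs no
external data.  The heavier end-to-end dataset is session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from methage import dmr, site_calling
from methage.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """200 kb genome, 10 genes, 3 planted promoter DMRs — quick unit-test food."""
    cfg = SimulationConfig(
        seed=11,
        chrom_sizes={"chr1": 200_000},
        n_genes=10,
        n_promoter_dmrs=3,
        n_random_de=2,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_calls(small_dataset):
    conv = site_calling.estimate_nonconversion_rate(small_dataset.spikein)
    c1 = site_calling.call_sites(small_dataset.report_g1, conv)
    c2 = site_calling.call_sites(small_dataset.report_g2, conv)
    return conv, c1, c2


@pytest.fixture(scope="session")
def medium_dataset():
    """600 kb, 40 genes, no random DE — enough genes for class statistics."""
    cfg = SimulationConfig(
        seed=4,
        chrom_sizes={"chr1": 600_000},
        n_genes=40,
        n_random_de=0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def medium_calls(medium_dataset):
    conv = site_calling.estimate_nonconversion_rate(medium_dataset.spikein)
    return conv, site_calling.call_sites(medium_dataset.report_g1, conv)


@pytest.fixture(scope="session")
def e2e_result():
    """Full pipeline on a 2 Mb genome: simulate -> call -> scan -> integrate.

    Shared by the smoke/recovery tests so the expensive stages run once.
    """
    import time

    from methage import integrate, io_formats
    from methage.synthetic_data import match_planted_dmrs

    t0 = time.monotonic()
    cfg = SimulationConfig(
        seed=20,
        chrom_sizes={"chr1": 2_000_000},
        n_genes=80,
        n_promoter_dmrs=10,
        n_random_de=8,
    )
    ds = simulate_dataset(cfg)
    conv = site_calling.estimate_nonconversion_rate(ds.spikein)
    c1 = site_calling.call_sites(ds.report_g1, conv)
    c2 = site_calling.call_sites(ds.report_g2, conv)
    dmrs = dmr.scan_and_call(c1, c2, ds.genome.chrom_sizes)
    matches = match_planted_dmrs(dmrs, ds.truth.planted_dmrs)
    elements = io_formats.gene_elements(ds.genome.genes, ds.genome.chrom_sizes)
    dmgs = integrate.map_dmrs_to_genes(dmrs, elements)
    joint = integrate.overlap_dmg_deg(dmgs, ds.expression)
    candidates = integrate.select_candidates(joint, methylation="Hyper", expression="Down")
    return {
        "elapsed": time.monotonic() - t0,
        "dataset": ds,
        "conv": conv,
        "calls": (c1, c2),
        "dmrs": dmrs,
        "matches": matches,
        "dmgs": dmgs,
        "joint": joint,
        "candidates": candidates,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
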