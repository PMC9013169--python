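"""Shared fixtures: small simulated F2 designs reused across the suite."""

import numpy as np
import pytest

import binqtl as bq
from binqtl.binmap import bins_from_sim


@pytest.fixture(scope="session")
def one_chrom_spec():
    return bq.GenomeSpec((bq.ChromosomeSpec("A01", 10_000_000, 100.0),),
                         snp_spacing=10_000)


@pytest.fixture(scope="session")
def noiseless_sim(one_chrom_spec):
    """High depth, no error: interval calls should mirror the truth."""
    return bq.simulate_f2_population(one_chrom_spec, (), n=200, mean_depth=50,
                                     error_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def study_sim(one_chrom_spec):
    """The shallow-coverage regime the pipeline targets (5.3x, 1% error)."""
    qtl = bq.QtlSpec("PH1", "A01", 5_050_000, a=1.0, d=0.5, residual_sd=1.0)
    return bq.simulate_f2_population(one_chrom_spec, (qtl,), n=249,
                                     mean_depth=5.3, error_rate=0.01, seed=7)


@pytest.fixture(scope="session")
def study_bins(study_sim):
    return {"A01": bins_from_sim(study_sim, "A01")}


@pytest.fixture(scope="session")
def study_map(study_bins):
    return bq.build_genetic_map(study_bins)


def f2_phenotype(sim, trait):
    ph = sim.phenotypes
    return (ph[ph.generation == "F2"].set_index("individual")
            .loc[sim.individuals, trait].to_numpy())
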