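"""Shared fixtures: small synthetic panels generated at test time."""

import numpy as np
import pandas as pd
import pytest

from plastiqtl import synthetic_data as sd


@pytest.fixture(scope="session")
def small_parents():
    """12 inbred parents x 80 SNPs on two chromosomes."""
    return sd.simulate_parents(12, 80,
                               chrom_lengths={"Chr01": 40_000_000,
                                              "Chr02": 30_000_000},
                               seed=7)


@pytest.fixture(scope="session")
def full_design():
    """The 7 x 25 partial factorial with 141 crosses."""
    return sd.make_cross_design(seed=11)


@pytest.fixture(scope="session")
def full_parents():
    return sd.simulate_parents(32, 300, seed=11,
                               sample_ids=sd.default_parent_ids())


@pytest.fixture(scope="session")
def full_hybrids(full_parents, full_design):
    return sd.make_hybrids(full_parents, full_design)


def toy_genotypes(dosage, chrom=None, pos=None):
    """Build a GenotypeMatrix from a raw dosage array for hand-worked cases."""
    from plastiqtl.io_formats import GenotypeMatrix
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    chrom = np.array(chrom if chrom is not None else ["Chr01"] * m, dtype=object)
    pos = np.asarray(pos if pos is not None else np.arange(1, m + 1) * 1000)
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(m)],
        chrom=chrom, pos=pos,
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["G"] * m, dtype=object),
        dosage=dosage)


@pytest.fixture
def toy_geno_factory():
    return toy_genotypes


def balanced_fw_frame(mu, g, h, b, trait="AC", location="HN-CS", noise=None,
                      seed=0):
    """Phenotype records satisfying the reaction-norm identity exactly."""
    g = np.asarray(g, float)
    h = np.asarray(h, float)
    b = np.asarray(b, float)
    y = mu + g[:, None] + h[None, :] + b[:, None] * h[None, :]
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, y.shape)
    rows = []
    for i in range(len(g)):
        for j in range(len(h)):
            rows.append({"hybrid_id": f"H{i + 1:03d}", "location_id": location,
                         "sowing_index": j + 1, "trait_name": trait,
                         "value": y[i, j]})
    return pd.DataFrame(rows)


@pytest.fixture
def fw_frame_factory():
    return balanced_fw_frame
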