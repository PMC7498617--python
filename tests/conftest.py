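"""Shared fixtures: tiny hand-built matrices and a small simulated study."""

from __future__ import annotations

import numpy as np
import pytest

from hybridrad.core_data import MISSING, GenotypeMatrix, Locus, SampleMeta


def make_matrix(loci, samples, genotypes, prov=None) -> GenotypeMatrix:
    """Build a matrix from per-locus lists of allele pairs (None = MISSING)."""
    gt = np.full((len(loci), len(samples), 2), MISSING, dtype=np.int16)
    for i, row in enumerate(genotypes):
        for j, cell in enumerate(row):
            if cell is not None:
                gt[i, j] = sorted(cell)
    return GenotypeMatrix(loci=list(loci), samples=list(samples), gt=gt, prov=prov)


def locus(chrom="chr1", pos=100, ref="A", alts=("C",), depth=10000, **kw) -> Locus:
    return Locus(chrom=chrom, pos=pos, ref=ref, alts=alts, total_depth=depth, **kw)


@pytest.fixture
def adult_panel():
    """2 ilex + 2 suber adults, 1 adult hybrid, 1 seedling of the hybrid."""
    return [
        SampleMeta("I1", "ilex", "adult"),
        SampleMeta("I2", "ilex", "adult"),
        SampleMeta("S1", "suber", "adult"),
        SampleMeta("S2", "suber", "adult"),
        SampleMeta("H1", "hybrid", "adult"),
        SampleMeta("K1", "hybrid", "seedling", mother_id="H1"),
    ]


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study, shared across tests."""
    from hybridrad.synthetic_data import SimConfig, simulate_study

    cfg = SimConfig(
        n_loci=240,
        n_adults_ilex=24,
        n_adults_suber=24,
        n_adult_hybrids=9,
        md_background=0.0,
        n_low_depth=10,
        seed=11,
    )
    return simulate_study(cfg, family_sizes=(4, 4, 4, 4, 4, 4, 4, 4, 4))


@pytest.fixture(scope="session")
def small_study_files(small_study, tmp_path_factory):
    from hybridrad.synthetic_data import write_simulation

    out = tmp_path_factory.mktemp("sim")
    return write_simulation(small_study, out)
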