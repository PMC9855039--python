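"""Shared builders for the test suite.

Most tests operate on small hand-constructed instrument sets; these helpers
build them with minimal noise so expected values are easy to derive.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrpipe.instruments import HarmonizedInstrument, MRDataset
from mrpipe.sumstats_io import VariantAssociation


def make_dataset(bx, sx, by, sy, ids=None) -> MRDataset:
    bx, sx, by, sy = map(np.atleast_1d, (bx, sx, by, sy))
    if ids is None:
        ids = [f"rs{i + 1}" for i in range(len(bx))]
    instruments = [
        HarmonizedInstrument(
            snp_id=ids[i], beta_exp=float(bx[i]), se_exp=float(sx[i]),
            beta_out=float(by[i]), se_out=float(sy[i]),
        )
        for i in range(len(bx))
    ]
    return MRDataset("exp", "out", "db", instruments)


def random_dataset(rng: np.random.Generator, j: int) -> MRDataset:
    """A random but well-behaved instrument set for oracle-equivalence checks."""
    bx = rng.uniform(0.03, 0.2, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.005, 0.02, j)
    by = 0.2 * bx + rng.normal(0, 0.02, j)
    sy = rng.uniform(0.01, 0.05, j)
    return make_dataset(bx, sx, by, sy)


def make_assoc(snp="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-10, eaf=0.3, n=10_000,
               trait="exposure") -> VariantAssociation:
    return VariantAssociation(
        snp_id=snp, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pval=pval, eaf=eaf, n=n, trait_id=trait,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230110)
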