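"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from stratiqtl import SimConfig, simulate_genotypes, simulate_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from stratiqtl.containers import ExpressionMatrix, GenotypeMatrix


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_per_breed=50,
        n_variants=400,
        n_genes=30,
        chrom_length=50_000_000,
        frac_shared_egenes=0.4,
        frac_specific_egenes=0.2,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_genotypes(small_study):
    return small_study[0]


def make_genotypes(dosage, positions=None, chrom="1", breeds=None):
    """Hand-rolled GenotypeMatrix from a samples x variants array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_s, n_v = dosage.shape
    if positions is None:
        positions = 1000 * np.arange(1, n_v + 1)
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(n_v)],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    if breeds is None:
        breeds = ["Duroc"] * n_s
    samples = pd.DataFrame({"id": [f"s{i}" for i in range(n_s)], "breed": breeds})
    return GenotypeMatrix(dosage, variants, samples)


def make_expression(values, unit="counts", tss=None, lengths=None, chrom="1"):
    """Hand-rolled ExpressionMatrix from a genes x samples array."""
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    if tss is None:
        tss = 100_000 * np.arange(1, n_g + 1)
    if lengths is None:
        lengths = np.full(n_g, 1000)
    genes = pd.DataFrame(
        {
            "id": [f"g{i}" for i in range(n_g)],
            "chrom": chrom,
            "tss": tss,
            "strand": "+",
            "length": lengths,
        }
    )
    return ExpressionMatrix(values, unit, genes, [f"s{j}" for j in range(n_s)])
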