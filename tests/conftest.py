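import numpy as np
import pandas as pd
import pytest

from kcgwas.formats import GenotypeDataset


@pytest.fixture(scope="session")
def example_studies():
    """The bundled 42-variant two-cohort table, split into study frames."""
    from kcgwas.datasets import kc_meta_example_studies

    return kc_meta_example_studies()


def make_dataset(dosages, phenotype=None, chrom=None, pos=None, ids=None,
                 covariates=None):
    """Small GenotypeDataset helper for hand-built dosage matrices."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else (1000 + 10 * np.arange(m)),
        "variant_id": ids if ids is not None else [f"v{j}" for j in range(m)],
        "effect_allele": ["A"] * m,
        "other_allele": ["G"] * m,
    })
    return GenotypeDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        variants=variants,
        dosages=dosages,
        phenotype=None if phenotype is None else np.asarray(phenotype),
        covariates=covariates,
    )


def random_ld_matrix(rng, ids, density=0.3):
    """Random symmetric r^2 matrix with unit diagonal (not necessarily PSD;
    the clumping algorithms only read pairwise values)."""
    m = len(ids)
    r2 = rng.random((m, m)) * (rng.random((m, m)) < density)
    r2 = np.triu(r2, 1)
    r2 = r2 + r2.T
    np.fill_diagonal(r2, 1.0)
    return pd.DataFrame(r2, index=ids, columns=ids)
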