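"""Bundled example data.

``load_kc_meta_example`` returns the 42-variant keratoconus
meta-analysis table: per-variant odds ratios, 95% CIs and p-values from
a newly genotyped Spanish case-control cohort (133 cases / 983
controls) and from the published Hardcastle et al. 2021 keratoconus
GWAS (4669 cases / 116,547 controls), together with the published
pooled OR, meta p-value, Cochran-Q tail probability and I^2 for each
variant.  The per-study ORs/CIs are printed at 2 decimals, so pooled
quantities recomputed from them agree with the published columns only
to that rounding.
"""

from __future__ import annotations

import importlib.resources as resources
import math

import pandas as pd

from .meta import beta_se_from_or_ci


def load_kc_meta_example() -> pd.DataFrame:
    """Load the raw 42-row example table (published columns as printed)."""
    with resources.files("kcgwas.data").joinpath("kc_meta_42.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"CHR": str})


_OTHER = {"A": "G", "T": "C", "C": "A", "G": "T"}  # synthetic non-effect allele


def kc_meta_example_studies():
    """Split the example into two study frames in the summary-stats dialect.

    Returns ``(spanish, hardcastle, reported)`` where the first two are
    summary-statistics DataFrames (log-odds converted from the printed
    ORs/CIs) and ``reported`` is the raw table with the published meta
    columns.  The table prints only the effect ("Ref") allele; a
    placeholder other allele is filled in, identical in both studies, so
    harmonization is a no-op.
    """
    raw = load_kc_meta_example()

    def study(prefix: str) -> pd.DataFrame:
        rows = []
        for r in raw.itertuples(index=False):
            orv = getattr(r, f"{prefix}_OR")
            lo = getattr(r, f"{prefix}_L95")
            hi = getattr(r, f"{prefix}_U95")
            beta, se = beta_se_from_or_ci(float(orv), float(lo), float(hi))
            ea = str(r.EA)
            rows.append((str(r.CHR), int(r.POS), str(r.ID), ea, _OTHER[ea],
                         beta, se, float(getattr(r, f"{prefix}_P")), float("nan")))
        return pd.DataFrame(rows, columns=["chrom", "pos", "variant_id",
                                           "effect_allele", "other_allele",
                                           "beta", "se", "p", "eaf"])

    return study("SPANISH"), study("HARDCASTLE"), raw
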