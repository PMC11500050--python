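"""Fixed-effects inverse-variance meta-analysis with heterogeneity.

The pooled estimate across k studies with log-odds effects ``beta_i``
and standard errors ``se_i`` uses weights ``w_i = 1/se_i**2``::

    beta_meta = sum(w_i * beta_i) / sum(w_i)
    se_meta   = sum(w_i) ** -0.5

Heterogeneity is summarised by Cochran's Q (``sum w_i (beta_i -
beta_meta)^2``, chi-square with k-1 df under homogeneity) and the I^2
percentage ``100 * max(0, (Q - df) / Q)``.

A caution on conventions: published association tables often print a
column labelled "Q" that holds the *tail probability* of Cochran's test
rather than the statistic itself.  The bundled 42-variant keratoconus
example is such a table -- recomputing the tail probabilities from its
per-study ORs/CIs reproduces the printed column (0.19, 0.01, ...),
whereas the raw Q statistic cannot.  ``MetaResults`` therefore exposes
both ``q_stat`` and ``q_p``; file output writes ``Q_P``.

Signal classification follows the gray-zone rescue design: a variant is
a *firm novel* signal when the meta-analysis is genome-wide significant,
the large published study alone was not (it sat in the gray zone above
5e-8), and the new replication cohort supports it at the nominal level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import SummaryStatRecord, harmonize_alleles

Z_975 = 1.959964

GW_THRESHOLD = 5e-8
NOMINAL = 0.05

CLASSES = ("firm_novel", "suggestive", "replicated_known", "not_significant")


@dataclass(frozen=True)
class StudyEffect:
    """One study's log-odds effect for one variant."""

    study_label: str
    beta: float
    se: float
    p: float | None = None

    def __post_init__(self):
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"{self.study_label}: se must be positive and finite")


def beta_se_from_or_ci(or_value: float, ci_low: float, ci_high: float,
                       level: float = 0.95) -> tuple[float, float]:
    """Convert an odds ratio with a Wald CI to (log-OR, SE).

    ``se = (ln U - ln L) / (2 * z)`` with ``z = Phi^{-1}((1+level)/2)``
    (1.959964 at the 95% level).
    """
    if not (0 < ci_low <= or_value <= ci_high):
        raise ValueError(
            f"invalid OR/CI: need 0 < L <= OR <= U, got {or_value} ({ci_low}-{ci_high})"
        )
    if ci_low == ci_high:
        raise ValueError("zero-width confidence interval")
    z = Z_975 if level == 0.95 else stats.norm.ppf(0.5 + level / 2.0)
    beta = math.log(or_value)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)
    return beta, se


def or_ci_from_beta_se(beta: float, se: float, level: float = 0.95):
    """Inverse of :func:`beta_se_from_or_ci` (round-trips to 1e-9)."""
    z = Z_975 if level == 0.95 else stats.norm.ppf(0.5 + level / 2.0)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


@dataclass
class MetaResults:
    """Pooled effect, heterogeneity and (optionally) classification."""

    variant_id: str | None
    beta_meta: float
    se_meta: float
    z: float
    p_meta: float
    k: int
    q_stat: float
    q_df: int
    q_p: float
    i2: float
    classification: str | None = None

    @property
    def or_meta(self) -> float:
        return math.exp(self.beta_meta)

    def conf_int(self, level: float = 0.95):
        _, lo, hi = or_ci_from_beta_se(self.beta_meta, self.se_meta, level)
        return lo, hi

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Fixed-effects inverse-variance meta-analysis",
            "=" * 44,
            f"variant:        {self.variant_id or '-'}",
            f"studies (k):    {self.k}",
            f"log-OR (beta):  {self.beta_meta:+.5f}  (SE {self.se_meta:.5f})",
            f"OR [95% CI]:    {self.or_meta:.3f}  [{lo:.3f}, {hi:.3f}]",
            f"z, p:           {self.z:+.3f}, {self.p_meta:.3e}",
        ]
        if self.k > 1:
            lines.append(
                f"Cochran Q:      {self.q_stat:.4f} on {self.q_df} df (p = {self.q_p:.3f})"
            )
            lines.append(f"I^2:            {self.i2:.2f}%")
        else:
            lines.append("heterogeneity:  NA (single study)")
        if self.classification is not None:
            lines.append(f"classification: {self.classification}")
        return "\n".join(lines)


class FixedEffectsMeta:
    """Fixed-effects model over a set of per-study effects.

    Parameters
    ----------
    effects : sequence of StudyEffect
        Harmonized per-study log-odds effects (same effect allele).
    variant_id : str, optional
        Carried through to the results.
    """

    def __init__(self, effects: Sequence[StudyEffect], variant_id: str | None = None):
        if len(effects) < 1:
            raise ValueError("at least one study effect required")
        self.effects = list(effects)
        self.variant_id = variant_id

    @classmethod
    def from_or_ci(cls, rows, variant_id=None, level: float = 0.95):
        """Build from ``(label, OR, L95, U95)`` tuples."""
        effects = []
        for label, orv, lo, hi in rows:
            beta, se = beta_se_from_or_ci(orv, lo, hi, level)
            effects.append(StudyEffect(label, beta, se))
        return cls(effects, variant_id)

    def fit(self) -> MetaResults:
        beta = np.array([e.beta for e in self.effects])
        se = np.array([e.se for e in self.effects])
        w = 1.0 / se**2
        beta_meta = float(np.sum(w * beta) / np.sum(w))
        se_meta = float(np.sum(w) ** -0.5)
        z = beta_meta / se_meta
        p_meta = float(2.0 * stats.norm.sf(abs(z)))
        k = len(self.effects)
        if k > 1:
            q = float(np.sum(w * (beta - beta_meta) ** 2))
            q_df = k - 1
            q_p = float(stats.chi2.sf(q, q_df))
            i2 = 0.0 if q == 0 else 100.0 * max(0.0, (q - q_df) / q)
        else:
            q, q_df, q_p, i2 = float("nan"), 0, float("nan"), float("nan")
        return MetaResults(self.variant_id, beta_meta, se_meta, z, p_meta,
                           k, q, q_df, q_p, i2)


def fixed_effects_meta(effects: Sequence[StudyEffect],
                       variant_id: str | None = None) -> MetaResults:
    """Functional convenience wrapper around :class:`FixedEffectsMeta`."""
    return FixedEffectsMeta(effects, variant_id).fit()


def classify_signal(p_meta: float, new_cohort_p: float, published_p: float,
                    gw_threshold: float = GW_THRESHOLD,
                    nominal: float = NOMINAL) -> str:
    """Classify a pooled signal against the two per-study p-values.

    ``new_cohort_p`` is the newly genotyped replication cohort,
    ``published_p`` the large prior GWAS whose gray zone is being
    rescued.

    * ``firm_novel``       -- meta genome-wide significant, prior study was
      not, and the new cohort is nominally associated;
    * ``suggestive``       -- as above but without nominal support in the
      new cohort;
    * ``replicated_known`` -- both meta and the prior study genome-wide
      significant;
    * ``not_significant``  -- meta above the genome-wide threshold.
    """
    if any(pd.isna(x) for x in (p_meta, new_cohort_p, published_p)):
        raise ValueError("all three p-values are required for classification")
    if p_meta >= gw_threshold:
        return "not_significant"
    if published_p < gw_threshold:
        return "replicated_known"
    return "firm_novel" if new_cohort_p < nominal else "suggestive"


META_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                "beta_meta", "se_meta", "or_meta", "z", "p_meta", "k",
                "q_stat", "q_p", "i2", "classification"]


def run_meta_table(study_a: pd.DataFrame, study_b: pd.DataFrame, *,
                   labels=("cohort_a", "cohort_b"),
                   reported_meta_p: dict | None = None,
                   gw_threshold: float = GW_THRESHOLD,
                   nominal: float = NOMINAL,
                   freq_tol: float = 0.2):
    """Meta-analyse two harmonizable summary-statistics tables.

    ``study_a`` plays the new-cohort role and ``study_b`` the published
    GWAS role in the classification.  Variants are matched by ID (falling
    back to chrom:pos), study-B effects are sign-flipped when the allele
    pair is swapped, and strand-ambiguous variants without confirming
    frequencies are skipped with a reason.

    ``reported_meta_p`` optionally maps variant IDs to externally
    reported meta p-values used for the classification gate -- relevant
    when the per-study inputs are 2-decimal published ORs/CIs whose
    rounding error exceeds the distance of a p-value from the
    genome-wide threshold; the pooled estimate itself is always
    recomputed.

    Returns ``(results_frame, skipped)`` where ``skipped`` is a list of
    ``(variant_id, reason)``.
    """
    if len(study_b) == 0:
        import warnings

        warnings.warn("study B is empty; no variants to meta-analyse", stacklevel=2)
        return pd.DataFrame(columns=META_COLUMNS), []

    b_by_id = {r.variant_id: r for r in study_b.itertuples(index=False)}
    b_by_pos = {(r.chrom, r.pos): r for r in study_b.itertuples(index=False)}
    rows, skipped = [], []
    for a in study_a.itertuples(index=False):
        b = b_by_id.get(a.variant_id) or b_by_pos.get((a.chrom, a.pos))
        if b is None:
            skipped.append((a.variant_id, "absent from study B"))
            continue
        try:
            sign = harmonize_alleles(a.effect_allele, a.other_allele,
                                     b.effect_allele, b.other_allele,
                                     a.eaf, b.eaf, freq_tol=freq_tol)
        except ValueError as exc:
            skipped.append((a.variant_id, str(exc)))
            continue
        effects = [
            StudyEffect(labels[0], a.beta, a.se, a.p),
            StudyEffect(labels[1], sign * b.beta, b.se, b.p),
        ]
        res = fixed_effects_meta(effects, a.variant_id)
        p_for_class = res.p_meta
        if reported_meta_p and a.variant_id in reported_meta_p:
            p_for_class = reported_meta_p[a.variant_id]
        res.classification = classify_signal(p_for_class, a.p, b.p,
                                             gw_threshold, nominal)
        rows.append((a.variant_id, a.chrom, a.pos, a.effect_allele, a.other_allele,
                     res.beta_meta, res.se_meta, res.or_meta, res.z, res.p_meta,
                     res.k, res.q_stat, res.q_p, res.i2, res.classification))
    return pd.DataFrame(rows, columns=META_COLUMNS), skipped


def write_meta_results(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={
        "variant_id": "ID", "chrom": "CHR", "pos": "POS",
        "effect_allele": "EA", "other_allele": "OA", "beta_meta": "BETA",
        "se_meta": "SE", "or_meta": "OR", "z": "Z", "p_meta": "P", "k": "K",
        "q_stat": "Q_STAT", "q_p": "Q_P", "i2": "I2",
        "classification": "CLASSIFICATION"})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
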