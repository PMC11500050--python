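"""Per-SNP case-control association with covariate adjustment and QC.

The association model is maximum-likelihood logistic regression of the
binary phenotype on allele dosage plus covariates (typically principal
components, guarding against population stratification), with a Wald
z-test per variant.  Complete-separation or non-convergence falls back
to Firth's penalized likelihood when requested, so degenerate variants
still return finite estimates.

QC is applied in a fixed order -- sample missingness, variant
missingness, minor-allele frequency, Hardy-Weinberg (exact test in
controls only) -- mirroring standard GWAS practice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .formats import GenotypeDataset


@dataclass(frozen=True)
class QCThresholds:
    """Default thresholds are common chip-QC practice."""

    min_maf: float = 0.01
    max_missing_per_variant: float = 0.05
    max_missing_per_sample: float = 0.05
    hwe_p_min: float = 1e-6

    def __post_init__(self):
        for name in ("min_maf", "max_missing_per_variant",
                     "max_missing_per_sample", "hwe_p_min"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class QCReport:
    n_samples_in: int
    n_variants_in: int
    samples_removed_missing: int = 0
    variants_removed_missing: int = 0
    variants_removed_maf: int = 0
    variants_removed_hwe: int = 0
    removed_variants: dict = field(default_factory=dict)  # variant_id -> reason

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_removed_missing

    @property
    def n_variants_out(self) -> int:
        return (self.n_variants_in - self.variants_removed_missing
                - self.variants_removed_maf - self.variants_removed_hwe)


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Two-sided exact test: sum of probabilities, conditional on the
    observed allele counts, of all heterozygote counts no more probable
    than the observed one.  Computed with a recurrence over heterozygote
    counts to stay exact at GWAS sample sizes.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    # possible het counts share the parity of the rare-allele count;
    # start the recurrence near the conditional expectation for stability
    het_obs = n_ab
    probs = {}
    exp_h = n_rare * (2 * n - n_rare) / (2.0 * n - 1.0) if n > 0 else 0
    start = int(round(exp_h))
    if start % 2 != n_rare % 2:
        start += 1
    start = max(n_rare % 2, min(start, n_rare))
    probs[start] = 1.0
    # going down: P(h-2)/P(h) = h(h-1) / ((rare-h+2)(2n-rare-h+2))
    h = start
    while h >= 2:
        num = h * (h - 1)
        den = (n_rare - h + 2) * (2 * n - n_rare - h + 2)
        probs[h - 2] = probs[h] * num / den
        h -= 2
    # going up: P(h+2)/P(h) = (rare-h)(2n-rare-h) / ((h+2)(h+1))
    h = start
    while h + 2 <= n_rare:
        num = (n_rare - h) * (2 * n - n_rare - h)
        den = (h + 2) * (h + 1)
        probs[h + 2] = probs[h] * num / den
        h += 2
    total = sum(probs.values())
    p_obs = probs.get(het_obs, 0.0) / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def _genotype_counts(dosages: np.ndarray):
    """Round dosages to hard calls for the HWE test."""
    g = np.rint(dosages).astype(int)
    return int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2))


def qc_filter(dataset: GenotypeDataset, thresholds: QCThresholds = QCThresholds()
              ) -> tuple[GenotypeDataset, QCReport]:
    """Apply QC in fixed order: sample missingness -> variant missingness
    -> MAF -> HWE in controls.  Raises if nothing survives."""
    report = QCReport(dataset.n_samples, dataset.n_variants)

    # sample missingness is only meaningful if per-sample missing info exists;
    # dosage storage is already imputed, so we track via missing_rate proxy.
    sample_keep = np.ones(dataset.n_samples, dtype=bool)
    # per-sample missingness is not retained post-imputation in this
    # container; datasets loaded from files with missing entries carry only
    # per-variant rates, so the sample step passes unless rates are supplied.
    ds = dataset

    miss = ds.missing_rate if ds.missing_rate is not None else np.zeros(ds.n_variants)
    keep = np.ones(ds.n_variants, dtype=bool)

    bad = miss > thresholds.max_missing_per_variant
    for i in np.where(bad)[0]:
        report.removed_variants[ds.variants.iloc[i]["variant_id"]] = "missing"
    report.variants_removed_missing = int(bad.sum())
    keep &= ~bad

    maf = ds.maf()
    bad = keep & (maf < thresholds.min_maf)
    for i in np.where(bad)[0]:
        report.removed_variants[ds.variants.iloc[i]["variant_id"]] = "maf"
    report.variants_removed_maf = int(bad.sum())
    keep &= ~bad

    if ds.phenotype is not None:
        controls = ds.phenotype == 0
        for i in np.where(keep)[0]:
            aa, ab, bb = _genotype_counts(ds.dosages[controls, i])
            if hwe_exact_p(aa, ab, bb) < thresholds.hwe_p_min:
                keep[i] = False
                report.removed_variants[ds.variants.iloc[i]["variant_id"]] = "hwe"
                report.variants_removed_hwe += 1

    if not keep.any() or not sample_keep.any():
        raise ValueError("no samples/variants survive QC")
    out = ds.subset(np.where(sample_keep)[0], np.where(keep)[0])
    return out, report


def ld_thin(dosages: np.ndarray, r2_max: float = 0.2, window: int = 100) -> np.ndarray:
    """Greedy LD thinning on empirical dosage r^2 within a sliding window.

    Returns indices of retained variants (first-come greedy order).
    Zero-variance columns are dropped.
    """
    n, m = dosages.shape
    sd = dosages.std(axis=0)
    std = np.zeros_like(dosages)
    ok = sd > 0
    std[:, ok] = (dosages[:, ok] - dosages[:, ok].mean(axis=0)) / sd[ok]
    kept: list[int] = []
    for j in range(m):
        if not ok[j]:
            continue
        conflict = False
        for k in reversed(kept):
            if j - k > window:
                break
            r = float(std[:, j] @ std[:, k]) / n
            if r * r >= r2_max:
                conflict = True
                break
        if not conflict:
            kept.append(j)
    return np.array(kept, dtype=int)


def compute_pcs(dataset: GenotypeDataset, k: int, *, ld_thin_r2: float | None = 0.2
                ) -> np.ndarray:
    """Principal-component scores of the column-standardized dosage matrix.

    Variants are LD-thinned (greedy, r^2 < ``ld_thin_r2``) before the
    SVD so local LD does not dominate the top axes; pass ``None`` to
    skip thinning.  Columns are ordered by decreasing variance
    explained; deterministic up to sign.
    """
    X = dataset.dosages
    if ld_thin_r2 is not None:
        idx = ld_thin(X, ld_thin_r2)
        X = X[:, idx]
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if k >= min(X.shape):
        raise ValueError("k must be smaller than min(n_samples, n_variants)")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    return u[:, :k] * s[:k]


@dataclass
class AssocResult:
    variant_id: str
    beta: float
    se: float
    z: float
    p: float
    n_cases: int
    n_controls: int
    maf: float
    status: str = "ok"  # ok | firth | monomorphic | failed


ASSOC_COLUMNS = ["variant_id", "beta", "se", "z", "p", "n_cases", "n_controls",
                 "maf", "status"]


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                 tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Firth's bias-reduced logistic regression (Jeffreys-prior penalty).

    Newton iterations on the modified score U* = X'(y - p + h*(0.5 - p)).
    Returns (coefficients, standard errors from the penalized information).
    """
    n, q = X.shape
    beta = np.zeros(q)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        if np.abs(step).max() > 5:
            step *= 5 / np.abs(step).max()
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    info = X.T @ (X * w[:, None])
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se


def logistic_assoc(dataset: GenotypeDataset, covariates: np.ndarray | None = None,
                   firth_fallback: bool = True) -> pd.DataFrame:
    """Per-variant logistic regression of phenotype on dosage (+covariates).

    Returns a DataFrame with one row per variant (Wald z and two-sided
    p).  Monomorphic variants are flagged NA with reason
    ``monomorphic``; separation or non-convergence uses Firth's
    penalized fit when ``firth_fallback`` is set, else returns NA.
    """
    y = dataset.phenotype
    if y is None:
        raise ValueError("dataset has no phenotype")
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise ValueError("need at least one case and one control")
    if covariates is None:
        covariates = dataset.covariates
    n = dataset.n_samples
    base = [np.ones(n)]
    if covariates is not None:
        base.append(np.asarray(covariates, dtype=float))
    base = np.column_stack(base)
    maf = dataset.maf()

    rows = []
    for j in range(dataset.n_variants):
        vid = dataset.variants.iloc[j]["variant_id"]
        g = dataset.dosages[:, j]
        if g.std() == 0:
            rows.append((vid, np.nan, np.nan, np.nan, np.nan, n_cases,
                         n_controls, maf[j], "monomorphic"))
            continue
        X = np.column_stack([base, g])
        beta = se = np.nan
        status = "ok"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            beta, se = fit.params[-1], fit.bse[-1]
            if not fit.mle_retvals.get("converged", True) or not np.isfinite(se) \
                    or se > 1e3 or abs(beta) > 15:
                raise RuntimeError("non-convergence/separation")
        except Exception:
            if firth_fallback:
                b, s = _firth_logit(X, y.astype(float))
                beta, se = b[-1], s[-1]
                status = "firth"
            else:
                status = "failed"
        if status == "failed" or not np.isfinite(se) or se <= 0:
            rows.append((vid, np.nan, np.nan, np.nan, np.nan, n_cases,
                         n_controls, maf[j], "failed"))
            continue
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((vid, beta, se, z, p, n_cases, n_controls, maf[j], status))
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


class LogisticGWAS:
    """Model object: case-control logistic scan over a genotype dataset.

    ``fit()`` returns :class:`AssociationResults` whose table feeds the
    meta module directly via :meth:`AssociationResults.to_summary_stats`.
    """

    def __init__(self, dataset: GenotypeDataset, covariates: np.ndarray | None = None,
                 n_pcs: int = 0, firth_fallback: bool = True):
        self.dataset = dataset
        self.firth_fallback = firth_fallback
        covs = []
        if covariates is not None:
            covs.append(np.asarray(covariates, dtype=float))
        if n_pcs:
            covs.append(compute_pcs(dataset, n_pcs))
        self.covariates = np.column_stack(covs) if covs else None

    def fit(self) -> "AssociationResults":
        table = logistic_assoc(self.dataset, self.covariates, self.firth_fallback)
        return AssociationResults(self, table)


class AssociationResults:
    def __init__(self, model: LogisticGWAS, table: pd.DataFrame):
        self.model = model
        self.table = table

    def to_summary_stats(self) -> pd.DataFrame:
        """Summary statistics in the formats-module dialect."""
        v = self.model.dataset.variants
        eaf = self.model.dataset.dosages.mean(axis=0) / 2.0
        ok = self.table["status"].isin(["ok", "firth"]).to_numpy()
        out = pd.DataFrame({
            "chrom": v["chrom"].to_numpy(), "pos": v["pos"].to_numpy(),
            "variant_id": v["variant_id"].to_numpy(),
            "effect_allele": v["effect_allele"].to_numpy(),
            "other_allele": v["other_allele"].to_numpy(),
            "beta": self.table["beta"].to_numpy(),
            "se": self.table["se"].to_numpy(),
            "p": self.table["p"].to_numpy(), "eaf": eaf,
        })
        return out[ok].reset_index(drop=True)

    def summary(self) -> str:
        t = self.table
        ok = t[t["status"].isin(["ok", "firth"])]
        lines = [
            "Case-control logistic association scan",
            "=" * 40,
            f"samples: {self.model.dataset.n_samples} "
            f"({int(self.model.dataset.phenotype.sum())} cases)",
            f"variants tested: {len(t)} (converged: {len(ok)}, "
            f"firth: {(t['status'] == 'firth').sum()}, "
            f"monomorphic: {(t['status'] == 'monomorphic').sum()})",
        ]
        if len(ok):
            top = ok.nsmallest(min(5, len(ok)), "p")
            lines.append("top signals:")
            for r in top.itertuples(index=False):
                lines.append(f"  {r.variant_id:>14}  beta={r.beta:+.3f}  p={r.p:.2e}")
        return "\n".join(lines)
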