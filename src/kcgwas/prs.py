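"""Clumping-and-thresholding polygenic risk scores.

The procedure re-implements the PRSice-style workflow: LD-clump the
base summary statistics (greedy, p-ordered, within a physical window),
then for each p-value cutoff in a grid score every target individual as
the weighted allele-dosage sum

    score_s = sum_j beta_j * dosage_{s,j}

over base SNPs passing the cutoff, fit ``phenotype ~ score +
covariates`` by logistic regression and report the Nagelkerke pseudo-R^2
of the score beyond the covariate-only model.  The best-fitting cutoff
maximises that delta-R^2.  Because the grid search itself is an
optimisation over cutoffs, the model-fit p-value is optimistic; the
label-permutation procedure repeats the *entire* search per permuted
phenotype and reports ``(1 + #{perm >= observed}) / (B + 1)``.

Scores use the sum (not average) convention; rank-based metrics and the
logistic fit are unchanged by that choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GenotypeDataset

DEFAULT_GRID = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


def fine_grid(step: float = 5e-5, upper: float = 0.5) -> tuple[float, ...]:
    """PRSice-like dense grid of cutoffs in steps of ``step``."""
    n = int(round(upper / step))
    return tuple(step * i for i in range(1, n + 1))


# ---------------------------------------------------------------------------
# clumping and scoring
# ---------------------------------------------------------------------------

def clump(base: pd.DataFrame, ld: pd.DataFrame, window_kb: float = 250.0,
          r2: float = 0.1) -> list[str]:
    """Greedy p-ordered LD clumping of base summary statistics.

    Keep the best remaining SNP; remove every SNP on the same chromosome
    within ``window_kb`` of it with r^2 >= ``r2``; repeat.  Returns the
    retained variant IDs in selection order.
    """
    window = window_kb * 1000.0
    order = base.sort_values(["p", "chrom", "pos"], kind="mergesort")
    ids = list(order["variant_id"])
    ld_idx = {v: i for i, v in enumerate(ld.index)}
    try:
        cols = np.array([ld_idx[v] for v in ids])
    except KeyError as exc:
        raise KeyError(f"variant {exc} missing from the LD matrix") from exc
    R = ld.to_numpy(dtype=float)[np.ix_(cols, cols)]
    chrom = order["chrom"].to_numpy()
    pos = order["pos"].to_numpy(dtype=float)
    alive = np.ones(len(ids), dtype=bool)
    kept: list[str] = []
    for i in range(len(ids)):
        if not alive[i]:
            continue
        kept.append(ids[i])
        hit = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window) \
            & (R[i] >= r2)
        hit[i] = False
        alive[hit] = False
        alive[i] = False
    return kept


def score_individuals(target: GenotypeDataset, weights: dict[str, float]
                      ) -> np.ndarray:
    """Per-sample weighted allele-dosage sum.

    Weight SNPs absent from the target are logged and skipped; raises
    when nothing overlaps.
    """
    vids = list(target.variants["variant_id"])
    idx = {v: i for i, v in enumerate(vids)}
    cols, betas, missing = [], [], []
    for vid, beta in weights.items():
        if vid in idx:
            cols.append(idx[vid])
            betas.append(beta)
        else:
            missing.append(vid)
    if not cols:
        raise ValueError("no weight SNPs overlap the target dataset")
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "%d weight SNP(s) absent from target, skipped", len(missing))
    return target.dosages[:, cols] @ np.asarray(betas)


# ---------------------------------------------------------------------------
# logistic fit internals
# ---------------------------------------------------------------------------

def _logit_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 40,
                tol: float = 1e-8) -> tuple[np.ndarray, float, bool]:
    """Newton-IRLS logistic fit; returns (beta, loglik, converged).

    Small fixed-design fits inside the permutation loop; cross-checked
    against statsmodels in the test suite.
    """
    n, q = X.shape
    beta = np.zeros(q)
    beta[0] = math.log(max(y.mean(), 1e-9) / max(1 - y.mean(), 1e-9))
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-12)
        z = eta + (y - p) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            return beta, _loglik(X, y, beta), False
        ll = _loglik(X, y, beta_new)
        if not np.isfinite(ll):
            return beta, ll_prev, False
        step = np.abs(beta_new - beta).max()
        beta = beta_new
        if step < tol or abs(ll - ll_prev) < 1e-10:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return beta, ll_prev, converged


def _loglik(X, y, beta) -> float:
    eta = np.clip(X @ beta, -30, 30)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 of a model against the intercept-only fit."""
    cox_snell = 1.0 - math.exp((2.0 / n) * (ll_null - ll_model))
    denom = 1.0 - math.exp((2.0 / n) * ll_null)
    return cox_snell / denom if denom > 0 else 0.0


def _fit_score_model(scores, y, covar):
    """Return (delta Nagelkerke R^2 of the score beyond covariates, Wald p)."""
    n = len(y)
    ones = np.ones((n, 1))
    X0 = ones if covar is None else np.column_stack([ones, covar])
    b0, ll0, conv0 = _logit_irls(X0, y)
    b_null, ll_null, _ = _logit_irls(ones, y)
    X1 = np.column_stack([X0, scores])
    b1, ll1, conv1 = _logit_irls(X1, y)
    if not (conv0 and conv1):
        raise RuntimeError("logistic fit did not converge")
    r2_full = nagelkerke_r2(ll1, ll_null, n)
    r2_cov = nagelkerke_r2(ll0, ll_null, n)
    # Wald p for the score coefficient
    eta = np.clip(X1 @ b1, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1 - p), 1e-12)
    info = X1.T @ (X1 * w[:, None])
    se = math.sqrt(np.linalg.pinv(info)[-1, -1])
    wald_p = 2.0 * stats.norm.sf(abs(b1[-1] / se)) if se > 0 else float("nan")
    return r2_full - r2_cov, wald_p


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class PRSResults:
    """Per-threshold fits and the chosen model."""

    clump_window_kb: float
    clump_r2: float
    threshold_grid: tuple[float, ...]
    per_threshold: pd.DataFrame  # threshold, n_snps, fit_r2, fit_p
    best_threshold: float
    best_n_snps: int
    best_fit_r2: float
    best_fit_p: float
    snp_weights: dict[str, float]
    scores: np.ndarray
    perm_p: float | None = None
    n_permutations: int = 0

    def summary(self) -> str:
        lines = [
            "Clumping-and-thresholding PRS model",
            "=" * 40,
            f"clump window / r^2:  {self.clump_window_kb:g} kb / {self.clump_r2:g}",
            f"grid size:           {len(self.threshold_grid)}",
            f"best cutoff:         p < {self.best_threshold:.3g}",
            f"SNPs in best model:  {self.best_n_snps}",
            f"Nagelkerke dR^2:     {self.best_fit_r2:.4f}  (p = {self.best_fit_p:.3e})",
        ]
        if self.perm_p is not None:
            lines.append(
                f"permutation p:       {self.perm_p:.3e}  (B = {self.n_permutations})")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Bar plot of delta-R^2 per threshold (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.per_threshold
        ax.bar(range(len(t)), t["fit_r2"], tick_label=[f"{x:.2g}" for x in t["threshold"]])
        ax.set_xlabel("p-value cutoff")
        ax.set_ylabel("Nagelkerke $\\Delta R^2$")
        return ax


@dataclass
class PRSEvaluation:
    auc: float
    auc_ci: tuple[float, float]
    case_mean: float
    control_mean: float
    t_stat: float
    t_p: float
    n_cases: int
    n_controls: int

    def summary(self) -> str:
        return "\n".join([
            "PRS discrimination",
            "=" * 40,
            f"AUC [95% CI]:  {self.auc:.3f}  [{self.auc_ci[0]:.3f}, {self.auc_ci[1]:.3f}]",
            f"mean score:    cases {self.case_mean:.4g}, controls {self.control_mean:.4g}",
            f"Welch t-test:  t = {self.t_stat:.3f}, p = {self.t_p:.3e}",
        ])


class PRSModel:
    """Clumping + thresholding PRS over a base study and a target cohort.

    Parameters
    ----------
    base : DataFrame
        Base summary statistics (formats-module dialect, log-odds betas).
    target : GenotypeDataset
        Genotyped cohort with binary phenotype.
    ld : DataFrame, optional
        r^2 matrix over base variants; required unless ``pre_clumped``.
    covariates : array, optional
        Per-sample covariate matrix included in every fit.
    grid : sequence of float
        P-value cutoffs to search.
    """

    def __init__(self, base: pd.DataFrame, target: GenotypeDataset,
                 ld: pd.DataFrame | None = None,
                 covariates: np.ndarray | None = None,
                 grid=DEFAULT_GRID, clump_window_kb: float = 250.0,
                 clump_r2: float = 0.1, pre_clumped: bool = False):
        if target.phenotype is None:
            raise ValueError("target dataset needs a phenotype")
        self.base = base
        self.target = target
        self.covariates = covariates if covariates is not None else target.covariates
        self.grid = tuple(sorted(grid))
        self.clump_window_kb = clump_window_kb
        self.clump_r2 = clump_r2
        if pre_clumped or ld is None:
            self.clumped = base
        else:
            keep = clump(base, ld, clump_window_kb, clump_r2)
            self.clumped = base[base["variant_id"].isin(keep)]
        self._prepare()

    def _prepare(self):
        """Precompute cumulative per-cutoff scores (phenotype-free)."""
        vids = list(self.target.variants["variant_id"])
        idx = {v: i for i, v in enumerate(vids)}
        rows = self.clumped[self.clumped["variant_id"].isin(idx)]
        rows = rows.sort_values("p", kind="mergesort")
        self._snp_order = list(rows["variant_id"])
        self._snp_p = rows["p"].to_numpy()
        self._snp_beta = rows["beta"].to_numpy()
        cols = [idx[v] for v in self._snp_order]
        G = self.target.dosages[:, cols] if cols else np.empty((self.target.n_samples, 0))
        self._cut_scores = {}
        self._cut_nsnps = {}
        for t in self.grid:
            sel = self._snp_p < t
            self._cut_nsnps[t] = int(sel.sum())
            self._cut_scores[t] = G[:, sel] @ self._snp_beta[sel] if sel.any() else None

    def _search(self, y: np.ndarray):
        """Grid search on a phenotype vector; returns per-threshold rows."""
        rows = []
        for t in self.grid:
            s = self._cut_scores[t]
            if s is None or np.std(s) == 0:
                continue
            try:
                r2, p = _fit_score_model(s, y, self.covariates)
            except RuntimeError:
                warnings.warn(f"cutoff {t:g}: fit did not converge, skipped",
                              stacklevel=2)
                continue
            rows.append((t, self._cut_nsnps[t], r2, p))
        if not rows:
            raise ValueError("no usable cutoff in the grid")
        return rows

    def fit(self) -> PRSResults:
        y = self.target.phenotype.astype(float)
        rows = self._search(y)
        table = pd.DataFrame(rows, columns=["threshold", "n_snps", "fit_r2", "fit_p"])
        best = table.loc[table["fit_r2"].idxmax()]
        t = float(best["threshold"])
        sel = self._snp_p < t
        weights = dict(zip(np.asarray(self._snp_order)[sel], self._snp_beta[sel]))
        return PRSResults(
            clump_window_kb=self.clump_window_kb, clump_r2=self.clump_r2,
            threshold_grid=self.grid, per_threshold=table,
            best_threshold=t, best_n_snps=int(best["n_snps"]),
            best_fit_r2=float(best["fit_r2"]), best_fit_p=float(best["fit_p"]),
            snp_weights=weights, scores=self._cut_scores[t].copy(),
        )

    def permutation_p(self, B: int = 1000, seed: int | None = None,
                      observed: PRSResults | None = None) -> float:
        """Label-permutation p for the best-model fit, re-optimising the
        cutoff for every permutation to correct grid-search optimism."""
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        obs = observed if observed is not None else self.fit()
        y = self.target.phenotype.astype(float)
        count = 0
        for _ in range(B):
            perm = rng.permutation(y)
            try:
                rows = self._search(perm)
            except ValueError:
                continue
            best_r2 = max(r[2] for r in rows)
            if best_r2 >= obs.best_fit_r2:
                count += 1
        return (1 + count) / (B + 1)


def threshold_search(base, target, covariates=None, grid=DEFAULT_GRID,
                     ld=None, **kwargs) -> PRSResults:
    """Functional wrapper: build a :class:`PRSModel` and fit it."""
    return PRSModel(base, target, ld=ld, covariates=covariates, grid=grid,
                    **kwargs).fit()


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def auc_mann_whitney(scores: np.ndarray, phenotype: np.ndarray) -> float:
    """AUC as the rank (Mann-Whitney) statistic; ties get half credit."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(phenotype)
    case = scores[y == 1]
    ctrl = scores[y == 0]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("need both cases and controls")
    ranks = stats.rankdata(np.concatenate([case, ctrl]))
    r_case = ranks[: len(case)].sum()
    u = r_case - len(case) * (len(case) + 1) / 2.0
    return float(u / (len(case) * len(ctrl)))


def _delong_variance(case: np.ndarray, ctrl: np.ndarray, auc: float) -> float:
    """DeLong's asymptotic variance of the AUC (placement values)."""
    m, n = len(case), len(ctrl)
    # V10_i: P(ctrl < case_i) with tie credit; V01_j analogous
    v10 = np.array([(np.sum(ctrl < c) + 0.5 * np.sum(ctrl == c)) / n for c in case])
    v01 = np.array([(np.sum(case > d) + 0.5 * np.sum(case == d)) / m for d in ctrl])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def evaluate(scores: np.ndarray, phenotype: np.ndarray,
             level: float = 0.95) -> PRSEvaluation:
    """Discrimination metrics: AUC with DeLong CI plus a Welch t-test."""
    y = np.asarray(phenotype)
    case = np.asarray(scores, dtype=float)[y == 1]
    ctrl = np.asarray(scores, dtype=float)[y == 0]
    auc = auc_mann_whitney(scores, y)
    var = _delong_variance(case, ctrl, auc)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    t_res = stats.ttest_ind(case, ctrl, equal_var=False)
    return PRSEvaluation(
        auc=auc, auc_ci=(max(0.0, auc - half), min(1.0, auc + half)),
        case_mean=float(case.mean()), control_mean=float(ctrl.mean()),
        t_stat=float(t_res.statistic), t_p=float(t_res.pvalue),
        n_cases=len(case), n_controls=len(ctrl),
    )
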