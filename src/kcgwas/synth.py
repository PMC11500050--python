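"""Synthetic data generation for every pipeline stage.

Genotypes come from a Gaussian-copula LD-block model: within a block of
adjacent variants the latent haplotype values are multivariate normal
with AR(1) correlation ``rho**|i-j|``; each of the two haplotypes per
sample is thresholded at the allele-frequency quantile and the two
indicator draws are summed to a dosage in {0, 1, 2}.  This gives
controllable block LD at a tiny fraction of the cost of a coalescent
simulation, at the price of no recombination-map realism.

Disease status is an additive logistic liability: ``P(case) =
logistic(intercept + sum_j beta_j * dosage_j)``; with ``center=True``
dosages are mean-centered inside the sum so the intercept alone sets
the expected case fraction.

The default cohort shape emulates a small replication cohort of 1116
samples with a 133/983 case-control split meta-analysed against a much
larger published study, whose summary statistics are generated directly
(beta = shared effect + optional heterogeneity perturbation; no
sampling-noise term, so planted gray-zone z-scores are exact on that
side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GenotypeDataset

CASE_FRACTION_DEFAULT = 133 / 1116  # ~0.119


@dataclass(frozen=True)
class SimulationConfig:
    """Two-cohort simulation settings.

    ``n_samples``/case split emulate the replication-cohort shape;
    ``cohort_b_se`` is the per-variant standard error of the large
    published study's effects (its CI widths imply ~0.03 at common
    MAF).  ``causal_beta`` entries are log-odds per allele applied at
    ``causal_index`` positions in both cohorts.
    """

    n_samples: int = 1116
    case_fraction: float = CASE_FRACTION_DEFAULT
    n_variants: int = 200
    block_size: int = 10
    rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_index: tuple[int, ...] = ()
    causal_beta: tuple[float, ...] = ()
    causal_maf: float | None = None  # pin causal-variant MAF (power control)
    cohort_b_se: float = 0.03
    heterogeneity_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_variants <= 0 or self.block_size <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if len(self.causal_index) != len(self.causal_beta):
            raise ValueError("causal_index and causal_beta lengths differ")
        if any(not np.isfinite(b) for b in self.causal_beta):
            raise ValueError("causal effects must be finite")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")


_ALLELES = ("A", "C", "G", "T")


def _block_chol(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def generate_genotypes(cfg: SimulationConfig, seed: int | None = None,
                       mafs: np.ndarray | None = None) -> GenotypeDataset:
    """Draw an LD-blocked dosage matrix (genotypes only).

    Variants are laid out 5 kb apart on one synthetic chromosome,
    block boundaries every ``cfg.block_size`` variants.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    m, n = cfg.n_variants, cfg.n_samples
    if mafs is None:
        mafs = rng.uniform(*cfg.maf_range, size=m)
        if cfg.causal_maf is not None and len(cfg.causal_index):
            mafs[list(cfg.causal_index)] = cfg.causal_maf
    thresholds = stats.norm.ppf(mafs)  # latent < q  =>  carry the effect allele
    dosages = np.empty((n, m))
    for start in range(0, m, cfg.block_size):
        size = min(cfg.block_size, m - start)
        chol = _block_chol(size, cfg.rho)
        for hap in range(2):
            z = rng.standard_normal((n, size)) @ chol.T
            carriers = z < thresholds[start:start + size]
            if hap == 0:
                dosages[:, start:start + size] = carriers
            else:
                dosages[:, start:start + size] += carriers
    # avoid strand-ambiguous (A/T, C/G) pairs so harmonization is clean
    _COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
    ea = rng.choice(_ALLELES, size=m)
    oa = np.array([rng.choice([x for x in _ALLELES if x not in (a, _COMP[a])])
                   for a in ea])
    variants = pd.DataFrame({
        "chrom": "1", "pos": 10_000 + 5_000 * np.arange(m),
        "variant_id": [f"snp{i}" for i in range(m)],
        "effect_allele": ea, "other_allele": oa,
    })
    return GenotypeDataset([f"s{i}" for i in range(n)], variants, dosages)


def simulate_phenotype(genotypes: GenotypeDataset, causal_effects: np.ndarray,
                       intercept: float, seed: int | None = None,
                       center: bool = False) -> np.ndarray:
    """Bernoulli phenotype under the additive logistic liability."""
    rng = np.random.default_rng(seed)
    if len(causal_effects) != genotypes.n_variants:
        raise ValueError("causal_effects must have one entry per variant")
    d = genotypes.dosages
    if center:
        d = d - d.mean(axis=0)
    eta = intercept + d @ np.asarray(causal_effects)
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    return (rng.random(genotypes.n_samples) < p).astype(int)


def intercept_for_case_fraction(frac: float) -> float:
    return math.log(frac / (1.0 - frac))


def generate_cohort(cfg: SimulationConfig, seed: int | None = None,
                    center_effects: bool = True) -> GenotypeDataset:
    """Genotypes plus phenotype with the configured planted effects."""
    seed = cfg.seed if seed is None else seed
    ds = generate_genotypes(cfg, seed=seed)
    beta = np.zeros(cfg.n_variants)
    for i, b in zip(cfg.causal_index, cfg.causal_beta):
        beta[i] = b
    ds.phenotype = simulate_phenotype(
        ds, beta, intercept_for_case_fraction(cfg.case_fraction),
        seed=seed + 1, center=center_effects)
    return ds


def empirical_ld(dataset: GenotypeDataset) -> pd.DataFrame:
    """Squared dosage correlation matrix keyed by variant ID."""
    X = dataset.dosages
    sd = X.std(axis=0)
    sd[sd == 0] = np.nan
    c = np.corrcoef(X, rowvar=False)
    r2 = np.nan_to_num(c**2, nan=0.0)
    np.fill_diagonal(r2, 1.0)
    ids = list(dataset.variants["variant_id"])
    return pd.DataFrame(r2, index=ids, columns=ids)


def generate_two_cohorts(cfg: SimulationConfig, shared_effects: np.ndarray,
                         heterogeneity_sd: float | None = None,
                         seed: int | None = None):
    """A genotyped cohort A plus directly generated cohort-B summary stats.

    Cohort B betas are ``shared + N(0, heterogeneity_sd^2)`` with
    standard error ``cfg.cohort_b_se`` and Wald p-values; no sampling
    noise is added, so cohort-B z-scores are controlled exactly.
    Returns ``(cohort_a_dataset, cohort_b_sumstats)``.
    """
    seed = cfg.seed if seed is None else seed
    het = cfg.heterogeneity_sd if heterogeneity_sd is None else heterogeneity_sd
    shared = np.asarray(shared_effects, dtype=float)
    if len(shared) != cfg.n_variants:
        raise ValueError("shared_effects must have one entry per variant")
    cfg_a = replace(cfg, causal_index=tuple(np.nonzero(shared)[0]),
                    causal_beta=tuple(shared[shared != 0]))
    cohort_a = generate_cohort(cfg_a, seed=seed)
    rng = np.random.default_rng(seed + 7)
    beta_b = shared + rng.normal(0.0, het, size=len(shared))
    se_b = np.full(len(shared), cfg.cohort_b_se, dtype=float)
    z = beta_b / se_b
    sumstats_b = cohort_a.variants.copy()
    sumstats_b["beta"] = beta_b
    sumstats_b["se"] = se_b
    sumstats_b["p"] = 2.0 * stats.norm.sf(np.abs(z))
    sumstats_b["eaf"] = cohort_a.dosages.mean(axis=0) / 2.0
    return cohort_a, sumstats_b


def gray_zone_config(n_variants: int = 200, seed: int = 0,
                     planted_beta: float = 0.42, z_published: float = 5.2
                     ) -> tuple[SimulationConfig, np.ndarray]:
    """Two planted gray-zone signals mirroring the rescue design.

    The planted effect gives the replication cohort an expected p of
    about 1e-3 (nominal but far from genome-wide), while the published
    cohort's z is pinned just above the genome-wide threshold
    (p ~ 2e-7); pooling pushes the pair past 5e-8.  Planted variants
    sit in different LD blocks at maximal MAF for power.
    """
    idx = (n_variants // 4, 3 * n_variants // 4)
    shared = np.zeros(n_variants)
    shared[list(idx)] = planted_beta
    cfg = SimulationConfig(
        n_variants=n_variants, seed=seed,
        causal_index=idx, causal_beta=(planted_beta, planted_beta),
        causal_maf=0.45,  # common planted variants, as for real rescue hits
        cohort_b_se=planted_beta / z_published,
    )
    return cfg, shared


# ---------------------------------------------------------------------------
# annotations and drugs
# ---------------------------------------------------------------------------

_RDB_CHOICES = ("1", "2", "3", "4", "5", "6", "7", None)


def generate_annotations(genes: list[str], seed: int = 0,
                         snps_per_gene: tuple[int, int] = (1, 4),
                         p_coding: float = 0.3):
    """Random per-(variant, gene) annotation rows spanning all tiers.

    Returns ``(annotation_frame, truth)`` where ``truth`` holds the
    ground-truth per-(gene, track) score and tier implied by the drawn
    evidence, computed by a direct restatement of the ledger rules.
    """
    from .prioritize import aggregate_evidence, score_genes

    rng = np.random.default_rng(seed)
    rows = []
    snp_counter = 0
    for gene in genes:
        n_snps = rng.integers(snps_per_gene[0], snps_per_gene[1] + 1)
        coding_gene = rng.random() < p_coding
        for _ in range(n_snps):
            vid = f"cand{snp_counter}"
            snp_counter += 1
            is_coding = coding_gene and rng.random() < 0.7
            consequence = (
                str(rng.choice(["synonymous", "inframe", "nonsynonymous", "frameshift"]))
                if is_coding else "noncoding")
            rows.append({
                "variant_id": vid, "gene_id": gene,
                "is_coding_effect": bool(is_coding), "consequence": consequence,
                "cadd": float(rng.choice([0.0, 5.0, 12.0, 25.0])),
                "pli": float(rng.choice([0.0, 0.5, 0.95])),
                "ncrvis": float(rng.normal(0.0, 1.0)),
                "rdb": rng.choice(_RDB_CHOICES),
                "eqtl": bool(rng.random() < 0.4),
                "ci_mapped": bool(rng.random() < 0.4),
                "protein_coding": bool(rng.random() < 0.7),
            })
    ann = pd.DataFrame(rows)
    truth = score_genes(aggregate_evidence(ann))
    return ann, truth


def generate_drug_table(genes_with_tiers: dict[str, int], seed: int = 0,
                        n_drugs: int = 30):
    """Random drug--target records; guarantees at least one approved drug
    hitting a tier-1 gene when one exists."""
    from .formats import DrugTargetRecord

    rng = np.random.default_rng(seed)
    genes = list(genes_with_tiers)
    if not genes:
        return []
    statuses = ("approved", "investigational", "withdrawn", "experimental")
    records = []
    for i in range(n_drugs):
        records.append(DrugTargetRecord(
            drug_name=f"drug{i}",
            status=str(rng.choice(statuses)),
            target_gene=str(rng.choice(genes)),
            action="inhibitor" if rng.random() < 0.5 else "agonist",
        ))
    tier1 = [g for g, t in genes_with_tiers.items() if t == 1]
    if tier1 and not any(r.status == "approved" and genes_with_tiers[r.target_gene] == 1
                         for r in records):
        records[0] = DrugTargetRecord("drug0", "approved",
                                      str(rng.choice(tier1)), "inhibitor")
    return records
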