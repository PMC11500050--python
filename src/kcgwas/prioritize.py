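"""Evidence-tier gene prioritization.

Genes tagged by candidate SNPs are scored on two separate tracks
depending on how their SNPs hit them.

Coding track (0-5 points): 1 point for pLI >= 0.9; CADD points for the
most deleterious associated SNP (2 if CADD >= 20, else 1 if >= 10,
non-cumulative); 1 point for a synonymous / non-frame-changing
consequence or 2 for a nonsynonymous / frame-changing one.

Non-coding track (0-9 points): the same pLI and CADD points, plus 1
point each for ncRVIS < 0, protein-coding gene, an eQTL effect and
chromatin-interaction mapping, plus RegulomeDB points for the most
significant category over the gene's SNPs (2 for categories 1/2, 1 for
3/4, 0 otherwise; sub-categories such as "2b" map by leading digit).

Tiers partition the score ranges: coding 4-5 / 2-3 / 0-1 and
non-coding 6-9 / 3-5 / 0-2 for tiers 1 / 2 / 3.  Per-criterion
aggregation over a gene's SNPs is best-evidence (max CADD, lowest RDB
category, OR over flags).  A gene hit by both coding and non-coding
SNPs receives one score per track; the pipeline-level tier of such a
gene is, by default, its best tier on either track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

CONSEQUENCE_LOW = {"synonymous", "inframe"}
CONSEQUENCE_HIGH = {"nonsynonymous", "frameshift"}


@dataclass(frozen=True)
class GeneEvidence:
    """Aggregated annotation evidence for one gene on one track."""

    gene_id: str
    track: str  # "coding" | "noncoding"
    pli: float = 0.0
    best_cadd: float = 0.0
    consequence_class: str | None = None  # coding track only
    ncrvis: float = 0.0
    protein_coding: bool = False
    eqtl: bool = False
    best_rdb: str | None = None
    ci_mapped: bool = False

    def __post_init__(self):
        if self.track not in ("coding", "noncoding"):
            raise ValueError(f"unknown track {self.track!r}")
        if self.best_cadd < 0:
            raise ValueError("best_cadd must be >= 0")


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    track: str
    score: int
    tier: int


def _cadd_points(cadd: float) -> int:
    return 2 if cadd >= 20 else (1 if cadd >= 10 else 0)


def _rdb_points(rdb: str | None) -> int:
    if rdb is None or not str(rdb):
        return 0
    lead = str(rdb)[0]
    if lead in ("1", "2"):
        return 2
    if lead in ("3", "4"):
        return 1
    return 0


def _coding_tier(score: int) -> int:
    return 1 if score >= 4 else (2 if score >= 2 else 3)


def _noncoding_tier(score: int) -> int:
    return 1 if score >= 6 else (2 if score >= 3 else 3)


def score_coding(e: GeneEvidence) -> GeneScore:
    """Coding-track ledger; raises when the consequence class is missing."""
    if e.track != "coding":
        raise ValueError("evidence is not on the coding track")
    if e.consequence_class is None:
        raise ValueError(f"{e.gene_id}: coding evidence without a consequence class")
    if e.consequence_class in CONSEQUENCE_HIGH:
        cons = 2
    elif e.consequence_class in CONSEQUENCE_LOW:
        cons = 1
    else:
        raise ValueError(f"{e.gene_id}: unknown consequence {e.consequence_class!r}")
    score = int(e.pli >= 0.9) + _cadd_points(e.best_cadd) + cons
    return GeneScore(e.gene_id, "coding", score, _coding_tier(score))


def score_noncoding(e: GeneEvidence) -> GeneScore:
    if e.track != "noncoding":
        raise ValueError("evidence is not on the non-coding track")
    score = (int(e.pli >= 0.9) + _cadd_points(e.best_cadd)
             + int(e.ncrvis < 0) + int(e.protein_coding) + int(e.eqtl)
             + _rdb_points(e.best_rdb) + int(e.ci_mapped))
    return GeneScore(e.gene_id, "noncoding", score, _noncoding_tier(score))


def score_evidence(e: GeneEvidence) -> GeneScore:
    return score_coding(e) if e.track == "coding" else score_noncoding(e)


def aggregate_evidence(annotations: pd.DataFrame,
                       candidate_snps: Iterable[str] | None = None
                       ) -> list[GeneEvidence]:
    """Collapse per-(variant, gene) annotation rows to per-(gene, track)
    best evidence.

    ``candidate_snps`` restricts to the locus module's candidates when
    given.  Coding rows are those with a coding consequence
    (``is_coding_effect``); a gene with both kinds of rows yields two
    evidence records.
    """
    df = annotations
    if candidate_snps is not None:
        df = df[df["variant_id"].isin(set(candidate_snps))]
    out: list[GeneEvidence] = []
    for (gene, coding), grp in sorted(
            df.groupby(["gene_id", "is_coding_effect"]),
            key=lambda kv: (kv[0][0], not kv[0][1])):
        rdbs = [str(r) for r in grp["rdb"] if r is not None and not pd.isna(r)]
        best_rdb = min(rdbs, key=lambda r: (int(r[0]), r)) if rdbs else None
        if coding:
            high = grp["consequence"].isin(CONSEQUENCE_HIGH).any()
            out.append(GeneEvidence(
                gene_id=gene, track="coding",
                pli=float(grp["pli"].max()), best_cadd=float(grp["cadd"].max()),
                consequence_class="nonsynonymous" if high else "synonymous",
            ))
        else:
            out.append(GeneEvidence(
                gene_id=gene, track="noncoding",
                pli=float(grp["pli"].max()), best_cadd=float(grp["cadd"].max()),
                ncrvis=float(grp["ncrvis"].min()),
                protein_coding=bool(grp["protein_coding"].any()),
                eqtl=bool(grp["eqtl"].any()), best_rdb=best_rdb,
                ci_mapped=bool(grp["ci_mapped"].any()),
            ))
    return out


def score_genes(evidence: Sequence[GeneEvidence]) -> pd.DataFrame:
    """Score a batch of evidence rows -> GENE/TRACK/SCORE/TIER frame."""
    scores = [score_evidence(e) for e in evidence]
    return pd.DataFrame(
        [(s.gene_id, s.track, s.score, s.tier) for s in scores],
        columns=["gene_id", "track", "score", "tier"],
    )


def combined_tiers(score_frame: pd.DataFrame, rule: str = "either") -> pd.Series:
    """Per-gene pipeline tier across tracks.

    ``either``: best (lowest-numbered) tier on any track; ``both``: a
    gene must reach the tier on every track it was scored on (i.e. the
    worst of its track tiers).
    """
    if rule not in ("either", "both"):
        raise ValueError("rule must be 'either' or 'both'")
    agg = score_frame.groupby("gene_id")["tier"]
    return agg.min() if rule == "either" else agg.max()


def geneset_enrichment(selected_genes: Iterable[str], geneset: Iterable[str],
                       background_n: int) -> tuple[int, float, float]:
    """One-sided hypergeometric enrichment of a selection in a gene set.

    Returns ``(overlap, expected, p)`` where ``p`` is the upper-tail
    probability of drawing at least the observed overlap when
    ``len(selected)`` genes are sampled from a universe of
    ``background_n`` containing ``len(geneset)`` set members.
    """
    sel = set(selected_genes)
    gs = set(geneset)
    if not gs:
        raise ValueError("empty gene set")
    if len(sel) > background_n or len(gs) > background_n:
        raise ValueError("selection or gene set larger than the background")
    overlap = len(sel & gs)
    expected = len(sel) * len(gs) / background_n
    p = float(stats.hypergeom.sf(overlap - 1, background_n, len(gs), len(sel)))
    return overlap, expected, p


def write_gene_scores(score_frame: pd.DataFrame, path, rule: str = "either") -> None:
    out = score_frame.rename(columns={"gene_id": "GENE", "track": "TRACK",
                                      "score": "SCORE", "tier": "TIER"})
    out.to_csv(path, sep="\t", index=False)
    combined = combined_tiers(score_frame, rule)
    summary_path = str(path) + ".tiers"
    combined.rename("TIER").rename_axis("GENE").reset_index().to_csv(
        summary_path, sep="\t", index=False)
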