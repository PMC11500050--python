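"""Genomic risk-locus definition from meta-analysis output plus LD.

The procedure mirrors the FUMA SNP2GENE conventions:

* independent significant SNPs (is-SNPs): genome-wide significant
  variants (p < 5e-8) that are mutually independent at r^2 < 0.6,
  selected greedily in ascending-p order;
* candidate SNPs: every variant (regardless of p) in LD (r^2 >= 0.6)
  with at least one is-SNP; is-SNPs are their own candidates;
* independent lead SNPs (il-SNPs): is-SNPs mutually independent at
  r^2 < 0.1, same greedy rule;
* risk loci: per-lead intervals spanning that lead's candidate SNPs,
  merged transitively when same-chromosome gaps are within 250 kb.

Gaps are measured between interval boundaries, not lead positions.
Intervals are half-open [start, end) in memory; the BED output is
0-based half-open as usual for BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MissingLDError(KeyError):
    """An r^2 lookup was required for a pair absent from the LD matrix."""


def _r2(ld: pd.DataFrame, a: str, b: str) -> float:
    try:
        return float(ld.at[a, b])
    except KeyError as exc:
        raise MissingLDError(f"no LD entry for pair ({a}, {b})") from exc


def _greedy_independent(snps: pd.DataFrame, ld: pd.DataFrame, r2_max: float) -> list[str]:
    """Greedy ascending-p selection; ties broken by (p, chrom, pos)."""
    order = snps.sort_values(["p", "chrom", "pos"], kind="mergesort")
    kept: list[str] = []
    for row in order.itertuples(index=False):
        if all(_r2(ld, row.variant_id, k) < r2_max for k in kept):
            kept.append(row.variant_id)
    return kept


def find_is_snps(results: pd.DataFrame, ld: pd.DataFrame,
                 p_thresh: float = 5e-8, r2_indep: float = 0.6) -> list[str]:
    """Independent significant SNPs (greedy p-ordered clumping).

    ``results`` needs columns ``variant_id, chrom, pos`` and a p-value
    column named either ``p_meta`` or ``p``.
    """
    pcol = "p_meta" if "p_meta" in results.columns else "p"
    sig = results[results[pcol] < p_thresh].rename(columns={pcol: "p"})
    return _greedy_independent(sig[["variant_id", "chrom", "pos", "p"]], ld, r2_indep)


def find_lead_snps(is_snps: list[str], results: pd.DataFrame, ld: pd.DataFrame,
                   r2_lead: float = 0.1) -> list[str]:
    """Independent lead SNPs: the is-SNPs re-clumped at r^2 < 0.1."""
    pcol = "p_meta" if "p_meta" in results.columns else "p"
    sub = results[results["variant_id"].isin(is_snps)].rename(columns={pcol: "p"})
    return _greedy_independent(sub[["variant_id", "chrom", "pos", "p"]], ld, r2_lead)


def find_candidate_snps(is_snps: list[str], all_results: pd.DataFrame,
                        ld: pd.DataFrame, r2_cand: float = 0.6) -> list[str]:
    """Every SNP (any p) with r^2 >= ``r2_cand`` to at least one is-SNP."""
    out = []
    is_set = set(is_snps)
    for vid in all_results["variant_id"]:
        if vid in is_set or any(_r2(ld, vid, s) >= r2_cand for s in is_snps):
            out.append(vid)
    return out


@dataclass
class RiskLocus:
    locus_id: str
    chrom: str
    start: int  # half-open [start, end) in 1-based coordinates
    end: int
    lead_snps: list[str] = field(default_factory=list)
    independent_significant_snps: list[str] = field(default_factory=list)
    candidate_snps: list[str] = field(default_factory=list)


def merge_risk_loci(leads: list[str], candidates: list[str],
                    results: pd.DataFrame, ld: pd.DataFrame,
                    is_snps: list[str] | None = None,
                    merge_window: int = 250_000,
                    r2_cand: float = 0.6) -> list[RiskLocus]:
    """Build per-lead intervals and merge transitively within ``merge_window``.

    Each lead's interval spans the positions of its candidate SNPs
    (those with r^2 >= ``r2_cand`` to the lead, plus the lead itself).
    Same-chromosome intervals whose boundary gap is <= ``merge_window``
    are merged; candidates of merged leads are pooled.  Output sorted by
    (chrom, start); each candidate lands in exactly one locus (ties go
    to the locus of the first lead claiming it in merge order).
    """
    pos = results.set_index("variant_id")[["chrom", "pos"]]
    if is_snps is None:
        is_snps = []
    intervals = []
    claimed: set[str] = set()
    for lead in leads:
        members = [lead] + [c for c in candidates
                            if c != lead and _r2(ld, lead, c) >= r2_cand]
        ps = [int(pos.at[m, "pos"]) for m in members]
        intervals.append({
            "chrom": str(pos.at[lead, "chrom"]),
            "start": min(ps), "end": max(ps) + 1,
            "leads": [lead], "members": set(members),
        })
    intervals.sort(key=lambda iv: (iv["chrom"], iv["start"], iv["end"]))
    merged: list[dict] = []
    for iv in intervals:
        if merged and merged[-1]["chrom"] == iv["chrom"] \
                and iv["start"] - merged[-1]["end"] <= merge_window:
            last = merged[-1]
            last["end"] = max(last["end"], iv["end"])
            last["start"] = min(last["start"], iv["start"])
            last["leads"] += iv["leads"]
            last["members"] |= iv["members"]
        else:
            merged.append(iv)
    loci = []
    is_set = set(is_snps)
    for i, iv in enumerate(merged, start=1):
        members = sorted(iv["members"] - claimed,
                         key=lambda m: (int(pos.at[m, "pos"]), m))
        claimed |= set(members)
        loci.append(RiskLocus(
            locus_id=f"locus_{i}", chrom=iv["chrom"],
            start=iv["start"], end=iv["end"],
            lead_snps=list(iv["leads"]),
            independent_significant_snps=[m for m in members if m in is_set],
            candidate_snps=members,
        ))
    return loci


def define_risk_loci(results: pd.DataFrame, ld: pd.DataFrame, *,
                     p_thresh: float = 5e-8, r2_indep: float = 0.6,
                     r2_cand: float = 0.6, r2_lead: float = 0.1,
                     merge_window: int = 250_000) -> list[RiskLocus]:
    """Full pipeline: is-SNPs -> candidates -> leads -> merged loci."""
    is_snps = find_is_snps(results, ld, p_thresh, r2_indep)
    cands = find_candidate_snps(is_snps, results, ld, r2_cand)
    leads = find_lead_snps(is_snps, results, ld, r2_lead)
    return merge_risk_loci(leads, cands, results, ld, is_snps=is_snps,
                           merge_window=merge_window, r2_cand=r2_cand)


def loci_to_bed(loci: list[RiskLocus]) -> pd.DataFrame:
    """BED-like frame (0-based half-open start/end on disk)."""
    return pd.DataFrame(
        [(l.chrom, l.start - 1, l.end - 1, l.locus_id, len(l.lead_snps),
          len(l.independent_significant_snps), len(l.candidate_snps))
         for l in loci],
        columns=["CHROM", "START", "END", "LOCUS_ID", "N_LEADS", "N_IS", "N_CAND"],
    )


def write_loci_bed(loci: list[RiskLocus], path) -> None:
    loci_to_bed(loci).to_csv(path, sep="\t", index=False)
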