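"""PPI edge enrichment and the drug-repositioning join.

``edge_enrichment`` asks whether a gene set induces more edges in a
protein-protein interaction network than equal-size random node sets
would: the null is B uniform draws (optionally degree-stratified) of
node sets from the network's universe, and the permutation p-value is
``(1 + #{null >= observed}) / (B + 1)``.  Uniform resampling is a
deliberate simplification of database-style background models; the
degree-stratified option draws within degree bins to control for hubs.

``drug_reposition`` joins tier-1/2 prioritized genes against a
drug--target table and reports hit counts by regulatory status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .formats import DrugTargetRecord


def read_network(path) -> nx.Graph:
    """2-column TSV edge list -> simple undirected graph (no self-loops)."""
    g = nx.Graph()
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str,
                     comment="#")
    for a, b in df.itertuples(index=False):
        if a != b:
            g.add_edge(a, b)
    return g


def edge_enrichment(genes: Iterable[str], network: nx.Graph, B: int = 10_000,
                    seed: int | None = None, degree_stratified: bool = False
                    ) -> tuple[int, float, float]:
    """Induced-subgraph edge count against a resampling null.

    Genes absent from the network are kept in the set (they contribute
    no edges), matching how interaction databases treat isolated query
    proteins.  Returns ``(observed, expected, p)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    genes = list(dict.fromkeys(genes))
    nodes = list(network.nodes)
    k = len(genes)
    if k > len(nodes):
        raise ValueError("gene set larger than the network's node universe")
    observed = network.subgraph([g for g in genes if g in network]).number_of_edges()
    rng = np.random.default_rng(seed)

    if degree_stratified:
        degs = np.array([network.degree(n) for n in nodes])
        bins = np.digitize(degs, np.quantile(degs, [0.25, 0.5, 0.75]))
        by_bin = {b: [n for n, nb in zip(nodes, bins) if nb == b] for b in set(bins)}
        gene_bins = [bins[nodes.index(g)] for g in genes if g in network]
        n_out = sum(1 for g in genes if g not in network)

        def draw():
            picked = []
            for b in gene_bins:
                pool = by_bin[b]
                picked.append(pool[rng.integers(len(pool))])
            # outside-network members draw uniformly, like their observed role
            extra = rng.choice(len(nodes), size=n_out, replace=False) if n_out else []
            return list(dict.fromkeys(picked)) + [nodes[i] for i in extra]
    else:
        def draw():
            idx = rng.choice(len(nodes), size=k, replace=False)
            return [nodes[i] for i in idx]

    null = np.empty(B)
    for b in range(B):
        null[b] = network.subgraph(draw()).number_of_edges()
    expected = float(null.mean())
    p = float((1 + np.sum(null >= observed)) / (B + 1))
    return observed, expected, p


@dataclass(frozen=True)
class DrugHit:
    drug_name: str
    status: str
    target_gene: str
    gene_tier: int
    action: str = ""


def drug_reposition(genes_with_tiers: Mapping[str, int],
                    drugs: Sequence[DrugTargetRecord],
                    status_filter: set[str] | None = frozenset({"approved"}),
                    tiers: set[int] = frozenset({1, 2})
                    ) -> tuple[list[DrugHit], dict]:
    """Join drugs onto tier-1/2 genes.

    Returns the deduplicated (drug, gene) hits passing ``status_filter``
    (pass ``None`` to keep all statuses) plus a counts dict covering
    every status before filtering.
    """
    eligible = {g: t for g, t in genes_with_tiers.items() if t in tiers}
    seen = set()
    all_hits: list[DrugHit] = []
    for rec in drugs:
        key = (rec.drug_name, rec.target_gene)
        if rec.target_gene in eligible and key not in seen:
            seen.add(key)
            all_hits.append(DrugHit(rec.drug_name, rec.status, rec.target_gene,
                                    eligible[rec.target_gene], rec.action))
    counts = {"total": len(all_hits), "unique_drugs": len({h.drug_name for h in all_hits})}
    for status in sorted({h.status for h in all_hits}):
        counts[status] = sum(1 for h in all_hits if h.status == status)
    hits = [h for h in all_hits
            if status_filter is None or h.status in status_filter]
    return hits, counts


def write_drug_hits(hits: Sequence[DrugHit], path) -> None:
    pd.DataFrame(
        [(h.drug_name, h.status, h.target_gene, h.gene_tier, h.action) for h in hits],
        columns=["DRUG", "STATUS", "TARGET", "GENE_TIER", "ACTION"],
    ).to_csv(path, sep="\t", index=False)
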