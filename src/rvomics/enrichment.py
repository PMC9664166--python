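"""GO over-representation analysis and enrichment-map term network.

Classic ORA: for each annotation term, the overlap between a selected
gene set and the term's genes is tested against the hypergeometric
distribution over a measured background universe (the genes that
entered the differential analysis, not the genome).  BH correction is
applied separately within each ontology domain (BP, CC, MF) since
results are reported per domain.  Enriched terms are arranged into an
enrichment-map style network whose edges connect terms sharing genes
(Jaccard similarity of their selected-gene sets).
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .proteomics import bh_adjust

log = logging.getLogger(__name__)

__all__ = ["DOMAINS", "hypergeom_enrich", "build_term_network"]

DOMAINS = ("BP", "CC", "MF")


def _validate_annotation(ann: pd.DataFrame) -> None:
    required = {"symbol", "go_id", "domain", "term_name"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    bad = set(ann["domain"]) - set(DOMAINS)
    if bad:
        raise ValueError(f"unknown ontology domains: {sorted(bad)}")


def hypergeom_enrich(
    selected: set[str],
    universe: set[str],
    ann: pd.DataFrame,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms.

    For a term annotating K of the N universe genes, of which k fall in
    the n selected genes, the p-value is the exact upper tail
    P(X >= k) with X ~ Hypergeometric(N, K, n).  Only terms with at
    least one selected gene are reported.  q is the BH-adjusted p within
    the term's domain; ``enriched`` flags q < ``q_max``.  Results are
    sorted by q then p.
    """
    selected = set(selected)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    _validate_annotation(ann)

    ann = ann[ann["symbol"].isin(universe)]
    N, n = len(universe), len(selected)
    records = []
    for (go_id, domain, term_name), genes in ann.groupby(
        ["go_id", "domain", "term_name"]
    )["symbol"]:
        term_genes = set(genes)
        K = len(term_genes)
        k = len(term_genes & selected)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        records.append(
            {"go_id": go_id, "term_name": term_name, "domain": domain,
             "k": k, "n": n, "K": K, "N": N, "p": p}
        )
    results = pd.DataFrame(
        records, columns=["go_id", "term_name", "domain", "k", "n", "K", "N", "p"]
    )
    results["q"] = 1.0
    for domain in DOMAINS:
        mask = results["domain"] == domain
        if mask.any():
            results.loc[mask, "q"] = bh_adjust(results.loc[mask, "p"].to_numpy())
    results["enriched"] = results["q"] < q_max
    results = results.sort_values(["q", "p", "go_id"], kind="stable")
    log.info("ORA: %d terms tested, %d enriched at q<%g",
             len(results), int(results["enriched"].sum()), q_max)
    return results.reset_index(drop=True)


def build_term_network(
    results: pd.DataFrame,
    ann: pd.DataFrame,
    selected: set[str] | None = None,
    jaccard_min: float = 0.25,
    q_max: float = 0.05,
) -> nx.Graph:
    """Enrichment-map network of significantly enriched terms.

    Nodes are terms with q < ``q_max``; an undirected edge joins two
    terms when the Jaccard similarity of their gene sets (restricted to
    ``selected`` when given) is at least ``jaccard_min``; the edge
    weight is the Jaccard value.  No self-edges; weights lie in (0, 1].
    """
    if results.empty:
        raise ValueError("no enrichment results to build a network from")
    _validate_annotation(ann)
    keep = results[results["q"] < q_max]
    gene_sets: dict[str, set[str]] = {}
    for go_id in keep["go_id"]:
        genes = set(ann.loc[ann["go_id"] == go_id, "symbol"])
        if selected is not None:
            genes &= set(selected)
        gene_sets[go_id] = genes

    graph = nx.Graph()
    for _, row in keep.iterrows():
        graph.add_node(
            row["go_id"], term_name=row["term_name"], domain=row["domain"],
            q=row["q"], k=row["k"],
        )
    terms = list(keep["go_id"])
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            union = gene_sets[a] | gene_sets[b]
            if not union:
                continue
            jaccard = len(gene_sets[a] & gene_sets[b]) / len(union)
            if jaccard >= jaccard_min and jaccard > 0:
                graph.add_edge(a, b, weight=jaccard)
    return graph
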