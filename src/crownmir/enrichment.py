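"""GO-term enrichment of differential sets against the array reference set.

Each term is tested with a two-sided Fisher exact test on the 2x2 table
(in-term / not-in-term x test set / rest of reference), BH-adjusted across
terms; a term is significant at q < alpha.  The reference set is the full
probe universe of the array, and the per-term percentages of the test set
and of the reference set are reported side by side (the paired-bar view).

``roll_to_level`` aggregates term hits to ancestors at a requested depth of
a parent DAG (depth = shortest path from a root, root depth 1), counting
each gene once per ancestor.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["TermMap", "enrich", "roll_to_level", "fisher_two_sided"]


class TermMap:
    """Term descriptions/levels plus the gene -> terms mapping."""

    def __init__(self, gene2term: dict[str, set], term_levels: dict[str, int],
                 descriptions: dict[str, str] | None = None):
        if not gene2term:
            raise ValueError("gene -> term mapping must be non-empty")
        if any(lvl < 1 for lvl in term_levels.values()):
            raise ValueError("term levels must be >= 1")
        self.gene2term = {g: set(ts) for g, ts in gene2term.items()}
        self.term_levels = dict(term_levels)
        self.descriptions = descriptions or {}

    def genes_for(self, term: str) -> set:
        return {g for g, ts in self.gene2term.items() if term in ts}

    def terms(self) -> list:
        out = set()
        for ts in self.gene2term.values():
            out |= ts
        return sorted(out)

    @classmethod
    def from_tsv(cls, gene2term_path, levels_path=None) -> "TermMap":
        g2t = pd.read_csv(gene2term_path, sep="\t")
        gene2term: dict[str, set] = {}
        for gene, term in zip(g2t.iloc[:, 0], g2t.iloc[:, 1]):
            gene2term.setdefault(gene, set()).add(term)
        levels = {}
        if levels_path is not None:
            lv = pd.read_csv(levels_path, sep="\t")
            levels = dict(zip(lv.iloc[:, 0], lv.iloc[:, 1].astype(int)))
        else:
            levels = {t: 1 for ts in gene2term.values() for t in ts}
        return cls(gene2term, levels)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for table [[a, b], [c, d]].

    Uses the minimum-likelihood rule: the sum of hypergeometric probabilities
    of all tables (with the observed margins) no more probable than the
    observed one.
    """
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def enrich(test_set: set, reference_set: set, term_map: TermMap,
           alpha: float = 0.05) -> pd.DataFrame:
    """Per-term enrichment table of ``test_set`` against ``reference_set``."""
    test_set = set(test_set)
    reference_set = set(reference_set)
    if not test_set <= reference_set:
        raise ValueError("test set must be a subset of the reference set")
    if not test_set:
        return pd.DataFrame(columns=["term", "level", "test_in_term", "ref_in_term",
                                     "test_pct", "ref_pct", "p", "q", "significant"])
    rest = reference_set - test_set
    rows = []
    for term in term_map.terms():
        genes = term_map.genes_for(term) & reference_set
        a = len(genes & test_set)             # in term, in test
        b = len(test_set) - a                 # not in term, in test
        c = len(genes & rest)                 # in term, rest of reference
        d = len(rest) - c
        rows.append({
            "term": term,
            "level": term_map.term_levels.get(term, 1),
            "test_in_term": a,
            "ref_in_term": len(genes),
            "test_pct": 100.0 * a / len(test_set),
            "ref_pct": 100.0 * len(genes) / len(reference_set),
            "p": fisher_two_sided(a, b, c, d),
        })
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].values)
    table["significant"] = table["q"] < alpha
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def roll_to_level(term_hits: dict[str, set], parent_edges: list[tuple[str, str]],
                  level: int = 3) -> pd.DataFrame:
    """Aggregate per-term gene hits to ancestors at the requested depth.

    ``term_hits`` maps term -> genes; ``parent_edges`` lists (child, parent).
    Depth is the shortest path from any root (a term with no parent), root
    depth 1.  A term at the requested level maps to itself; genes are
    counted once per ancestor.  Raises on a cyclic parent table.
    """
    g = nx.DiGraph()
    for child, parent in parent_edges:
        g.add_edge(parent, child)  # edges point root -> leaf
    for term in term_hits:
        g.add_node(term)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("parent table contains a cycle")
    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    depth = {}
    for root in roots:
        for node, d in nx.single_source_shortest_path_length(g, root).items():
            depth[node] = min(depth.get(node, d + 1), d + 1)

    ancestors_at_level: dict[str, set] = {}
    for term in term_hits:
        if depth.get(term) == level:
            ancestors_at_level[term] = {term}
            continue
        found = set()
        for anc in nx.ancestors(g, term) if term in g else set():
            if depth.get(anc) == level:
                found.add(anc)
        ancestors_at_level[term] = found

    pooled: dict[str, set] = {}
    for term, genes in term_hits.items():
        for anc in ancestors_at_level[term]:
            pooled.setdefault(anc, set()).update(genes)
    rows = [{"term": t, "level": level, "n_genes": len(gs), "genes": sorted(gs)}
            for t, gs in sorted(pooled.items())]
    return pd.DataFrame(rows, columns=["term", "level", "n_genes", "genes"])
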