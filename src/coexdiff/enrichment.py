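"""Hypergeometric over-representation analysis against GMT gene sets.

Query gene sets (condition-specific hubs, high-betweenness brokers, or
network modules) are tested for enrichment of annotation terms with the
upper-tail hypergeometric test and Benjamini-Hochberg FDR control, at a dual
cutoff p <= 0.05 and q <= 0.05. Module-level enrichments feed two
cross-condition summaries: a functional-similarity matrix (Jaccard on
enriched-term sets) and per-term module-representation counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "EnrichmentTable",
    "read_gmt",
    "write_gmt",
    "hypergeom_ora",
    "module_enrichment",
    "functional_similarity",
    "process_representation",
]


@dataclass
class AnnotationSet:
    """Term -> gene-set annotations with a background universe."""

    terms: Dict[str, set]
    descriptions: Dict[str, str] = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for t, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {t!r} has an empty gene set")
        if not self.universe:
            self.universe = set().union(*self.terms.values())


@dataclass
class EnrichmentTable:
    """Full and cutoff-filtered term over-representation results."""

    table: pd.DataFrame       # all tested terms
    significant: pd.DataFrame  # rows with p <= p_cut and q <= q_cut
    p_cut: float
    q_cut: float
    n_query_dropped: int = 0

    def significant_terms(self) -> set:
        return set(self.significant["term"])


def read_gmt(path) -> AnnotationSet:
    """Read a tab-delimited GMT file (term, description, gene ids...)."""
    terms: Dict[str, set] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            terms[fields[0]] = set(g for g in fields[2:] if g)
            descriptions[fields[0]] = fields[1]
    return AnnotationSet(terms=terms, descriptions=descriptions)


def write_gmt(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations.terms):
            desc = annotations.descriptions.get(term, "")
            genes = "\t".join(sorted(annotations.terms[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def hypergeom_ora(
    query: Iterable,
    annotations: AnnotationSet,
    p_cut: float = 0.05,
    q_cut: float = 0.05,
    min_term: int = 2,
    universe: Optional[set] = None,
) -> EnrichmentTable:
    """Upper-tail hypergeometric over-representation test per term.

    For each term with at least ``min_term`` genes in the universe,
    p = P(X >= n_overlap) with X ~ Hypergeom(N=|universe|, K=n_term,
    n=|query|); q-values are Benjamini-Hochberg over all tested terms.
    Query genes outside the universe are dropped (count recorded).
    """
    universe = set(universe) if universe is not None else set(annotations.universe)
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    dropped = len(query - universe)
    query &= universe
    if not query:
        raise ValueError("no query genes inside the annotation universe")
    n_universe = len(universe)
    n_query = len(query)

    rows = []
    for term in sorted(annotations.terms):
        term_genes = annotations.terms[term] & universe
        if len(term_genes) < min_term:
            continue
        overlap = sorted(query & term_genes)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, n_universe, len(term_genes), n_query))
        rows.append({
            "term": term,
            "description": annotations.descriptions.get(term, ""),
            "n_query": n_query,
            "n_term": len(term_genes),
            "n_overlap": k,
            "n_universe": n_universe,
            "p": min(p, 1.0),
            "overlap_genes": ",".join(overlap),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
        significant = table[(table["p"] <= p_cut) & (table["q"] <= q_cut)]
    else:
        table = pd.DataFrame(columns=["term", "description", "n_query", "n_term",
                                      "n_overlap", "n_universe", "p",
                                      "overlap_genes", "q"])
        significant = table
    return EnrichmentTable(table=table, significant=significant.copy(),
                           p_cut=p_cut, q_cut=q_cut, n_query_dropped=dropped)


def module_enrichment(
    partition,
    annotations: AnnotationSet,
    min_module: int = 5,
    universe: Optional[set] = None,
    p_cut: float = 0.05,
    q_cut: float = 0.05,
) -> Dict[int, EnrichmentTable]:
    """ORA for every partition module of at least ``min_module`` genes.

    The background defaults to the annotation universe (typically all
    post-filter genes of the expression matrix, not only network nodes);
    pass ``universe`` to override. Undersized modules are skipped.
    """
    assign = partition.assignment if hasattr(partition, "assignment") else dict(partition)
    modules: Dict[int, set] = {}
    for gene, m in assign.items():
        modules.setdefault(m, set()).add(gene)
    out: Dict[int, EnrichmentTable] = {}
    for m in sorted(modules, key=str):
        genes = modules[m]
        if len(genes) < min_module:
            continue
        try:
            out[m] = hypergeom_ora(genes, annotations, p_cut=p_cut, q_cut=q_cut,
                                   universe=universe)
        except ValueError:
            continue  # module entirely outside the universe
    return out


def functional_similarity(
    enrich_a: Mapping[int, EnrichmentTable],
    enrich_b: Mapping[int, EnrichmentTable],
) -> pd.DataFrame:
    """Jaccard similarity of enriched-term sets between module pairs.

    Modules with no enriched terms produce NaN rows/columns (flagged empty,
    not zero by convention).
    """
    idx = sorted(enrich_a, key=str)
    cols = sorted(enrich_b, key=str)
    mat = pd.DataFrame(np.nan, index=idx, columns=cols, dtype=float)
    for a in idx:
        ta = enrich_a[a].significant_terms()
        if not ta:
            continue
        for b in cols:
            tb = enrich_b[b].significant_terms()
            if not tb:
                continue
            mat.loc[a, b] = len(ta & tb) / len(ta | tb)
    return mat


def process_representation(
    enrich_a: Mapping[int, EnrichmentTable],
    enrich_b: Mapping[int, EnrichmentTable],
    top_k: int = 50,
) -> pd.DataFrame:
    """How many modules of each condition are enriched for each term.

    Returns per-term counts for both conditions and their difference,
    sorted by absolute difference descending, truncated to ``top_k`` rows.
    """
    count_a: Dict[str, int] = {}
    count_b: Dict[str, int] = {}
    for counts, enrich in ((count_a, enrich_a), (count_b, enrich_b)):
        for table in enrich.values():
            for term in table.significant_terms():
                counts[term] = counts.get(term, 0) + 1
    terms = sorted(set(count_a) | set(count_b))
    df = pd.DataFrame({
        "term": terms,
        "n_modules_a": [count_a.get(t, 0) for t in terms],
        "n_modules_b": [count_b.get(t, 0) for t in terms],
    })
    df["difference"] = df["n_modules_b"] - df["n_modules_a"]
    df["abs_difference"] = df["difference"].abs()
    df = df.sort_values(["abs_difference", "term"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    return df.head(top_k)
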