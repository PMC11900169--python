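"""Mutual-information co-expression network inference.

Expression is discretized per gene, pairwise mutual information (MI) is
computed with the plug-in (maximum-likelihood) estimator, and an undirected
network is built by keeping the top pairs at a high percentile of the MI
distribution. A marginal-preserving permutation null certifies that the
retained threshold exceeds what independence alone produces.

MI is reported in nats. Only the rank order of pair values matters for
percentile thresholding, so the logarithm base cannot change the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix

__all__ = [
    "DiscretizedMatrix",
    "MIResult",
    "CoexNetwork",
    "NullModelReport",
    "discretize",
    "mutual_information",
    "mi_matrix",
    "threshold_by_percentile",
    "percentile_sweep",
    "permutation_null",
]

DEFAULT_PERCENTILE = 99.99
SWEEP_PERCENTILES = (99.9999, 99.999, 99.99, 99.9, 99.0, 98.0, 90.0, 80.0)


@dataclass
class DiscretizedMatrix:
    """Per-gene integer bin codes (genes x samples)."""

    bins: np.ndarray  # int codes, genes x samples
    n_bins: int
    method: str
    gene_ids: pd.Index
    sample_ids: pd.Index
    source_provenance: list = field(default_factory=list)


@dataclass
class MIResult:
    """Condensed upper-triangular pairwise MI values (nats).

    ``mi[condensed_index(i, j)]`` holds MI between genes i < j in the order
    of ``gene_ids`` (scipy squareform convention).
    """

    gene_ids: pd.Index
    mi: np.ndarray
    n_samples: int
    estimator: str = "plugin"

    @property
    def n_pairs(self) -> int:
        return self.mi.size

    def pair_value(self, i: int, j: int) -> float:
        n = len(self.gene_ids)
        if i == j:
            raise ValueError("diagonal excluded from MIResult")
        i, j = (i, j) if i < j else (j, i)
        return float(self.mi[n * i - i * (i + 1) // 2 + (j - i - 1)])


@dataclass
class CoexNetwork:
    """Undirected MI-weighted co-expression graph of genes with degree >= 1."""

    graph: nx.Graph
    threshold_value: float
    percentile: float

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def edge_set(self) -> frozenset:
        return frozenset(frozenset(e) for e in self.graph.edges)


@dataclass
class NullModelReport:
    n_permutations: int
    percentile: float
    observed_threshold: float
    null_thresholds: np.ndarray
    null_mi_quantiles: pd.Series
    empirical_p: float
    seed: int


def default_n_bins(n_samples: int) -> int:
    """Cube-root rule for the number of discretization bins."""
    return max(2, math.ceil(round(n_samples ** (1.0 / 3.0), 9)))


def discretize(
    matrix: NormalizedMatrix,
    method: str = "equal_frequency",
    n_bins: Optional[int] = None,
) -> DiscretizedMatrix:
    """Bin each gene's expression values independently across samples.

    ``equal_frequency`` assigns balanced rank blocks whose occupancies
    differ by at most one sample (ties resolved by stable sample order);
    ``equal_width`` splits the
    observed [min, max] range evenly. A constant gene lands entirely in
    bin 0 under either method (documented, not an error).
    """
    values = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    if n_bins is None:
        n_bins = default_n_bins(n_samples)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_samples < n_bins:
        raise ValueError("need at least n_bins samples")

    codes = np.zeros((n_genes, n_samples), dtype=np.int64)
    if method == "equal_frequency":
        # balanced rank blocks: occupancies differ by at most one sample
        pos_codes = np.arange(n_samples) * n_bins // n_samples
        for g in range(n_genes):
            row = values[g]
            if row.max() == row.min():
                continue  # constant gene: all bin 0
            order = np.argsort(row, kind="stable")
            codes[g, order] = pos_codes
    elif method == "equal_width":
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = hi - lo
        nonconst = (span > 0).ravel()
        scaled = np.zeros_like(values)
        scaled[nonconst] = (values[nonconst] - lo[nonconst]) / span[nonconst]
        codes = np.minimum((scaled * n_bins).astype(np.int64), n_bins - 1)
        codes[~nonconst] = 0
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    return DiscretizedMatrix(
        bins=codes,
        n_bins=int(codes.max()) + 1 if codes.size else n_bins,
        method=method,
        gene_ids=matrix.gene_ids,
        sample_ids=matrix.sample_ids,
        source_provenance=list(matrix.provenance),
    )


def mutual_information(x_bins: Sequence[int], y_bins: Sequence[int]) -> float:
    """Plug-in MI estimate (nats) between two discrete code vectors."""
    x = np.asarray(x_bins, dtype=np.int64)
    y = np.asarray(y_bins, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("x_bins and y_bins must have equal length")
    if y.tobytes() < x.tobytes():
        x, y = y, x  # canonical argument order => exact symmetry
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    bx, by = x.max() + 1, y.max() + 1
    joint = np.bincount(x * by + y, minlength=bx * by).astype(float).reshape(bx, by)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))


def _plogp_sum(counts: np.ndarray) -> np.ndarray:
    """Sum of c*ln(c) along the last axis, with 0 ln 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(counts > 0, counts * np.log(np.where(counts > 0, counts, 1.0)), 0.0)
    return t.sum(axis=-1)


def mi_matrix(
    disc: DiscretizedMatrix,
    genes_subset: Optional[Iterable[str]] = None,
    chunk_size: int = 512,
) -> MIResult:
    """All-pairs plug-in MI via the entropy identity MI = H(x)+H(y)-H(x,y).

    Joint histograms for whole gene blocks are accumulated with one matrix
    product per bin pair, so the result is independent of the chunking.
    """
    bins = disc.bins
    gene_ids = disc.gene_ids
    if genes_subset is not None:
        keep = gene_ids.get_indexer(pd.Index(genes_subset))
        if (keep < 0).any():
            raise KeyError("genes_subset contains unknown gene ids")
        bins = bins[keep]
        gene_ids = gene_ids[keep]
    n_genes, n = bins.shape
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    n_bins = int(bins.max()) + 1
    log_n = math.log(n)

    # indicator tensor: for each bin level a, the genes x samples membership
    indicators = np.stack(
        [(bins == a).astype(np.float64) for a in range(n_bins)], axis=0
    )
    marg_counts = indicators.sum(axis=2)  # n_bins x n_genes
    h_marg = log_n - _plogp_sum(marg_counts.T) / n  # per-gene entropy (nats)

    mi = np.empty(n_genes * (n_genes - 1) // 2, dtype=np.float64)
    for i0 in range(0, n_genes, chunk_size):
        i1 = min(i0 + chunk_size, n_genes)
        for j0 in range(i0, n_genes, chunk_size):
            j1 = min(j0 + chunk_size, n_genes)
            s_joint = np.zeros((i1 - i0, j1 - j0))
            for a in range(n_bins):
                left = indicators[a, i0:i1]
                for b in range(n_bins):
                    counts = left @ indicators[b, j0:j1].T
                    mask = counts > 0
                    s_joint[mask] += counts[mask] * np.log(counts[mask])
            h_joint = log_n - s_joint / n
            block = h_marg[i0:i1, None] + h_marg[None, j0:j1] - h_joint
            for ii in range(i0, i1):
                jstart = max(j0, ii + 1)
                if jstart >= j1:
                    continue
                off = n_genes * ii - ii * (ii + 1) // 2 - ii - 1
                mi[off + jstart : off + j1] = block[ii - i0, jstart - j0 : j1 - j0]
    np.maximum(mi, 0.0, out=mi)  # clip tiny negative rounding
    return MIResult(gene_ids=gene_ids, mi=mi, n_samples=n)


def _pair_order(mi: MIResult) -> np.ndarray:
    """Pair ranking: MI descending, ties by lexicographic gene-pair order."""
    n = len(mi.gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    lex = np.argsort(np.argsort(mi.gene_ids.astype(str)))  # lexicographic rank
    a = np.minimum(lex[iu], lex[ju])
    b = np.maximum(lex[iu], lex[ju])
    return np.lexsort((b, a, -mi.mi))


def threshold_by_percentile(
    mi: MIResult, percentile: float = DEFAULT_PERCENTILE
) -> CoexNetwork:
    """Keep the top (100 - percentile)% of gene pairs by MI.

    k = floor((1 - percentile/100) * n_pairs) edges are retained; boundary
    ties are broken by lexicographic gene-pair order so the build is
    deterministic and two same-universe networks get identical edge counts.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    n = len(mi.gene_ids)
    n_pairs = mi.n_pairs
    # guard against float noise when the tail fraction times n_pairs is integral
    k = int(math.floor(round((100.0 - percentile) * n_pairs / 100.0, 9)))
    if k == 0:
        raise ValueError(
            f"percentile {percentile} keeps zero of {n_pairs} pairs; lower it"
        )
    order = _pair_order(mi)[:k]
    iu, ju = np.triu_indices(n, k=1)
    g = nx.Graph()
    ids = mi.gene_ids
    for idx in order:
        g.add_edge(ids[iu[idx]], ids[ju[idx]], weight=float(mi.mi[idx]))
    threshold_value = float(mi.mi[order[-1]])
    return CoexNetwork(graph=g, threshold_value=threshold_value,
                       percentile=float(percentile))


def percentile_sweep(
    mi: MIResult, percentiles: Sequence[float] = SWEEP_PERCENTILES
) -> pd.DataFrame:
    """Basic network metrics per candidate percentile threshold.

    Percentiles keeping zero pairs yield all-zero rows rather than errors.
    """
    rows = []
    for p in percentiles:
        try:
            net = threshold_by_percentile(mi, p)
        except ValueError:
            rows.append({"percentile": p, "n_nodes": 0, "n_edges": 0,
                         "n_components": 0, "largest_component": 0,
                         "transitivity": 0.0})
            continue
        comps = list(nx.connected_components(net.graph))
        rows.append({
            "percentile": p,
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "n_components": len(comps),
            "largest_component": max((len(c) for c in comps), default=0),
            "transitivity": float(nx.transitivity(net.graph)),
        })
    return pd.DataFrame(rows)


def _pair_mi_from_bins(bins: np.ndarray, i_arr: np.ndarray, j_arr: np.ndarray) -> np.ndarray:
    """Vectorized plug-in MI for an explicit list of gene pairs."""
    n = bins.shape[1]
    nb = int(bins.max()) + 1
    p = i_arr.size
    codes = bins[i_arr] * nb + bins[j_arr]  # p x n
    offset = np.arange(p, dtype=np.int64)[:, None] * (nb * nb)
    joint = np.bincount((codes + offset).ravel(), minlength=p * nb * nb)
    joint = joint.reshape(p, nb, nb).astype(np.float64)
    s_joint = _plogp_sum(joint.reshape(p, -1))
    s_x = _plogp_sum(joint.sum(axis=2))
    s_y = _plogp_sum(joint.sum(axis=1))
    log_n = math.log(n)
    mi = (log_n - s_x / n) + (log_n - s_y / n) - (log_n - s_joint / n)
    return np.maximum(mi, 0.0)


def permutation_null(
    matrix: NormalizedMatrix,
    n_perm: int = 100,
    percentile: float = DEFAULT_PERCENTILE,
    seed: int = 0,
    method: str = "equal_frequency",
    n_bins: Optional[int] = None,
    max_pairs: int = 100_000,
) -> NullModelReport:
    """Marginal-preserving permutation null for the MI threshold.

    Each permutation independently shuffles every gene's sample order,
    destroying all between-gene dependence while preserving per-gene
    marginals, then recomputes the MI distribution on a fixed random
    subsample of at most ``max_pairs`` gene pairs and records the null
    percentile value. The empirical p is the fraction of permutations whose
    null threshold reaches the observed one.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    disc = discretize(matrix, method=method, n_bins=n_bins)
    bins = disc.bins
    n_genes, n_samples = bins.shape
    n_pairs = n_genes * (n_genes - 1) // 2
    iu, ju = np.triu_indices(n_genes, k=1)
    if n_pairs > max_pairs:
        pick = rng.choice(n_pairs, size=max_pairs, replace=False)
        iu, ju = iu[pick], ju[pick]
    observed = _pair_mi_from_bins(bins, iu, ju)
    observed_threshold = float(np.percentile(observed, percentile))

    null_thresholds = np.empty(n_perm)
    pooled_quantiles = np.zeros(5)
    qs = (5, 25, 50, 75, 95)
    for p_idx in range(n_perm):
        # shuffling bin codes per gene == shuffling samples then re-binning
        perm_bins = np.empty_like(bins)
        for g in range(n_genes):
            perm_bins[g] = bins[g, rng.permutation(n_samples)]
        null_mi = _pair_mi_from_bins(perm_bins, iu, ju)
        null_thresholds[p_idx] = np.percentile(null_mi, percentile)
        pooled_quantiles += np.percentile(null_mi, qs) / n_perm
    empirical_p = float(np.mean(null_thresholds >= observed_threshold))
    return NullModelReport(
        n_permutations=n_perm,
        percentile=float(percentile),
        observed_threshold=observed_threshold,
        null_thresholds=null_thresholds,
        null_mi_quantiles=pd.Series(pooled_quantiles, index=[f"q{q}" for q in qs]),
        empirical_p=empirical_p,
        seed=seed,
    )
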