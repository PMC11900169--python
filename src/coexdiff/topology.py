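"""Topological characterization and cross-condition network comparison.

Degree distributions and their parametric fits, two-sample K-S comparison,
transitivity, diameter, betweenness, hub / high-betweenness gene sets,
edge-set Jaccard similarity, neighbor-gain analysis for condition-specific
hubs, induced subgraphs, and a degree-preserving rewiring null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .minet import CoexNetwork

__all__ = [
    "DegreeSummary",
    "degree_summary",
    "fit_gamma_loglog",
    "fit_candidate_distributions",
    "ks_two_sample",
    "transitivity",
    "diameter_and_components",
    "edge_jaccard",
    "betweenness",
    "top_fraction",
    "compare_gene_sets",
    "neighbor_gain",
    "induced_subgraph",
    "rewiring_null",
    "centrality_table",
]


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CoexNetwork) else net


@dataclass
class DegreeSummary:
    degrees: pd.Series            # node -> degree
    histogram: pd.Series          # degree k -> p(k), sums to 1
    cumulative: pd.Series         # degree k -> P(K >= k), non-increasing


def degree_summary(net) -> DegreeSummary:
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = pd.Series(dict(g.degree()), name="degree").sort_index()
    counts = deg.value_counts().sort_index()
    hist = counts / counts.sum()
    cumulative = hist[::-1].cumsum()[::-1]
    return DegreeSummary(degrees=deg, histogram=hist, cumulative=cumulative)


def fit_gamma_loglog(summary: DegreeSummary) -> float:
    """Scaling exponent from least squares on the log-log degree histogram.

    Fits ln p(k) = c - gamma * ln k over degrees with nonzero frequency and
    returns gamma (the negated slope). Requires >= 3 support points.
    """
    hist = summary.histogram[summary.histogram > 0]
    hist = hist[hist.index > 0]
    if len(hist) < 3:
        raise ValueError(
            f"log-log fit needs >= 3 distinct degrees, got {len(hist)}"
        )
    slope, _ = np.polyfit(np.log(hist.index.to_numpy(dtype=float)),
                          np.log(hist.to_numpy()), 1)
    return float(-slope)


def _zipf_loglik(s: float, k: np.ndarray) -> float:
    return float(-s * np.log(k).sum() - k.size * np.log(special.zeta(s, 1)))


def fit_candidate_distributions(summary: DegreeSummary) -> pd.DataFrame:
    """Maximum-likelihood fits of candidate degree distributions with AIC.

    Candidates: discrete power law (Zipf, k >= 1), Poisson, geometric
    (discrete exponential, k >= 1), negative binomial, and normal on the
    log-degree scale (a log-normal density over k). Rows that cannot be
    fitted on degenerate data carry NaNs. AIC = 2 * n_params - 2 * loglik;
    the lowest AIC row is flagged.
    """
    k = summary.degrees.to_numpy(dtype=float)
    if k.size < 10:
        raise ValueError("need >= 10 nodes for distribution fitting")
    rows = []

    def add(name, n_params, loglik, params):
        aic = 2 * n_params - 2 * loglik if np.isfinite(loglik) else np.nan
        rows.append({"distribution": name, "n_params": n_params,
                     "loglik": loglik, "aic": aic, "params": params})

    # discrete power law (Zipf), support k >= 1
    try:
        res = optimize.minimize_scalar(
            lambda s: -_zipf_loglik(s, k), bounds=(1.0001, 20.0),
            method="bounded")
        add("power_law", 1, _zipf_loglik(res.x, k), {"alpha": float(res.x)})
    except Exception:
        add("power_law", 1, np.nan, {})

    lam = k.mean()
    add("poisson", 1, float(stats.poisson.logpmf(k, lam).sum()), {"lam": lam})

    p_geom = 1.0 / k.mean()  # support k >= 1
    add("geometric", 1, float(stats.geom.logpmf(k, p_geom).sum()),
        {"p": p_geom})

    # negative binomial via direct likelihood optimization
    try:
        mean, var = k.mean(), k.var()
        r0 = mean**2 / max(var - mean, 1e-6)

        def nb_nll(theta):
            r = math.exp(theta[0])
            p = r / (r + math.exp(theta[1]))
            return -float(stats.nbinom.logpmf(k, r, p).sum())

        res = optimize.minimize(nb_nll, [math.log(max(r0, 1e-3)),
                                         math.log(mean)], method="Nelder-Mead")
        r = math.exp(res.x[0])
        mu = math.exp(res.x[1])
        add("negative_binomial", 2, -float(res.fun),
            {"r": r, "p": r / (r + mu)})
    except Exception:
        add("negative_binomial", 2, np.nan, {})

    # normal on log-degree == log-normal density over k (Jacobian included)
    logk = np.log(k)
    mu, sigma = logk.mean(), logk.std()
    if sigma > 0:
        ll = float(stats.norm.logpdf(logk, mu, sigma).sum() - logk.sum())
        add("lognormal", 2, ll, {"mu": mu, "sigma": sigma})
    else:
        add("lognormal", 2, np.nan, {})

    table = pd.DataFrame(rows)
    table["is_best"] = False
    if table["aic"].notna().any():
        table.loc[table["aic"].idxmin(), "is_best"] = True
    return table


def ks_two_sample(deg_a: Sequence[float], deg_b: Sequence[float],
                  method: str = "asymp") -> tuple:
    """Two-sided two-sample Kolmogorov-Smirnov test on degree samples."""
    res = stats.ks_2samp(np.asarray(deg_a, dtype=float),
                         np.asarray(deg_b, dtype=float), method=method)
    return float(res.statistic), float(res.pvalue)


def transitivity(net) -> float:
    """Global clustering: 3 * triangles / connected triples (0 if no triples)."""
    return float(nx.transitivity(_graph(net)))


def diameter_and_components(net) -> tuple:
    """(diameter over finite paths, component count, largest component size).

    On disconnected graphs the diameter is the maximum eccentricity within
    any connected component, i.e. the longest finite shortest path.
    """
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = [g.subgraph(c) for c in nx.connected_components(g)]
    diameter = max(nx.diameter(c) if c.number_of_nodes() > 1 else 0
                   for c in comps)
    return diameter, len(comps), max(c.number_of_nodes() for c in comps)


def edge_jaccard(net_a, net_b) -> float:
    """|E_a intersect E_b| / |E_a union E_b| over unordered gene pairs."""
    ea = {frozenset(e) for e in _graph(net_a).edges}
    eb = {frozenset(e) for e in _graph(net_b).edges}
    union = ea | eb
    if not union:
        raise ValueError("both edge sets empty")
    return len(ea & eb) / len(union)


def betweenness(net) -> pd.Series:
    """Unnormalized shortest-path betweenness (undirected, each pair once)."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return pd.Series(nx.betweenness_centrality(g, normalized=False),
                     name="betweenness").sort_index()


def top_fraction(scores: pd.Series, fraction: float = 0.10) -> Set:
    """Genes in the top ``fraction`` of scores, boundary ties included.

    k = ceil(fraction * n) genes are taken by descending score and any gene
    tied with the k-th score joins the set, so an all-tied input returns
    every gene.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    scores = pd.Series(scores)
    k = math.ceil(fraction * len(scores))
    cutoff = scores.sort_values(ascending=False).iloc[k - 1]
    return set(scores.index[scores >= cutoff])


def compare_gene_sets(set_a: Iterable, set_b: Iterable) -> dict:
    """Shared / exclusive partition of two gene sets, percentages over the union."""
    a, b = set(set_a), set(set_b)
    union = a | b
    shared = a & b
    denom = max(len(union), 1)
    return {
        "shared": shared,
        "a_only": a - b,
        "b_only": b - a,
        "n_shared": len(shared),
        "n_a_only": len(a - b),
        "n_b_only": len(b - a),
        "pct_shared": 100.0 * len(shared) / denom,
        "pct_a_only": 100.0 * len(a - b) / denom,
        "pct_b_only": 100.0 * len(b - a) / denom,
    }


def neighbor_gain(net_a, net_b, genes: Iterable) -> dict:
    """Neighbors acquired in network B relative to network A, per query gene.

    A gene absent from A contributes its full B neighborhood as gain; a gene
    absent from both networks is an error. The common gained set contains
    the genes gained by *every* query gene.
    """
    ga, gb = _graph(net_a), _graph(net_b)
    gains: Dict = {}
    for gene in genes:
        if gene not in gb:
            if gene not in ga:
                raise KeyError(f"gene {gene!r} absent from both networks")
            gains[gene] = set()
            continue
        nb = set(gb.neighbors(gene))
        na = set(ga.neighbors(gene)) if gene in ga else set()
        gains[gene] = nb - na
    common = set.intersection(*gains.values()) if gains else set()
    mean_gain = float(np.mean([len(v) for v in gains.values()])) if gains else 0.0
    return {"gains": gains, "common_gained": common, "mean_gain": mean_gain}


def induced_subgraph(net, genes: Iterable) -> CoexNetwork:
    """Subgraph on the given genes with all internal edges; unknown ids dropped."""
    g = _graph(net)
    genes = set(genes)
    present = genes & set(g.nodes)
    sub = nx.Graph(g.subgraph(present))
    out = CoexNetwork(
        graph=sub,
        threshold_value=getattr(net, "threshold_value", float("nan")),
        percentile=getattr(net, "percentile", float("nan")),
    )
    out.n_dropped = len(genes) - len(present)
    return out


def rewiring_null(net, n_rewires: Optional[int] = None, n_replicates: int = 100,
                  seed: int = 0, with_diameter: bool = False) -> dict:
    """Degree-preserving double-edge-swap null for transitivity (and diameter).

    Each replicate applies ``n_rewires`` successful swaps (>= 10 |E| required)
    to a copy of the network; the degree sequence is exactly preserved. The
    empirical p is the fraction of replicates whose null transitivity reaches
    the observed value.
    """
    g = _graph(net)
    m = g.number_of_edges()
    if n_rewires is None:
        n_rewires = 10 * m
    if n_rewires < 10 * m:
        raise ValueError("n_rewires must be at least 10 * |E|")
    obs_t = transitivity(net)
    rng = np.random.default_rng(seed)
    null_t = np.empty(n_replicates)
    null_d = np.empty(n_replicates) if with_diameter else None
    for r in range(n_replicates):
        h = nx.Graph(g)
        nx.double_edge_swap(h, nswap=n_rewires, max_tries=100 * n_rewires,
                            seed=int(rng.integers(2**31)))
        null_t[r] = nx.transitivity(h)
        if with_diameter:
            null_d[r] = diameter_and_components(
                CoexNetwork(h, float("nan"), float("nan")))[0]
    out = {
        "observed_transitivity": obs_t,
        "null_transitivity_mean": float(null_t.mean()),
        "null_transitivity_sd": float(null_t.std()),
        "empirical_p": float(np.mean(null_t >= obs_t)),
        "null_transitivity": null_t,
        "n_rewires": n_rewires,
        "seed": seed,
    }
    if with_diameter:
        out["null_diameter_mean"] = float(null_d.mean())
        out["null_diameter_sd"] = float(null_d.std())
    return out


def centrality_table(net, hub_fraction: float = 0.10) -> pd.DataFrame:
    """Per-gene degree and betweenness with hub / high-betweenness flags."""
    g = _graph(net)
    deg = pd.Series(dict(g.degree()), name="degree").sort_index()
    btw = betweenness(net)
    hubs = top_fraction(deg, hub_fraction)
    brokers = top_fraction(btw, hub_fraction)
    return pd.DataFrame({
        "degree": deg,
        "betweenness": btw,
        "is_hub": deg.index.isin(list(hubs)),
        "is_high_betweenness": btw.index.isin(list(brokers)),
    })
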