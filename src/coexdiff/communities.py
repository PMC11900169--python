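"""Map-equation community detection and cross-condition partition comparison.

Networks are partitioned by minimizing the two-level map equation -- the
expected per-step description length, in bits, of a random walk encoded with
one index codebook over modules and one codebook per module:

    L(M) = q H(Q) + sum_m p_m H(P_m)

where node visit rates are proportional to degree (strength when weighted),
q is the total module-exit rate and p_m the module codebook usage rate. The
optimizer performs Louvain-style node moves scored by the exact change in L,
followed by module-merge passes, with random restarts; the best trial is
kept. Partitions are scored by Newman modularity Q (globally and per
module) and compared across conditions with normalized mutual information
and module-membership Jaccard matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .minet import CoexNetwork

__all__ = [
    "Partition",
    "ModuleSimilarity",
    "map_equation",
    "infomap_partition",
    "newman_modularity",
    "per_module_q",
    "nmi",
    "membership_similarity",
]

_EPS = 1e-12


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CoexNetwork) else net


@dataclass
class Partition:
    """Node -> module assignment with quality scores and provenance."""

    assignment: Dict[Hashable, int]
    n_modules: int
    map_equation_bits: float
    modularity_q: float
    per_module_q: Dict[int, float] = field(default_factory=dict)
    trials: int = 0
    seed: Optional[int] = None

    def modules(self) -> Dict[int, set]:
        out: Dict[int, set] = {}
        for node, m in self.assignment.items():
            out.setdefault(m, set()).add(node)
        return out


@dataclass
class ModuleSimilarity:
    """Jaccard matrix between the modules of two partitions."""

    matrix: pd.DataFrame          # modules_a x modules_b Jaccard values
    matches: list                 # greedy one-to-one (module_a, module_b, J)
    preservation_counts: Dict[float, int]
    best_match_jaccard: pd.Series  # per a-module J of its greedy match (or 0)


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0 else 0.0


def _assignment(partition) -> Mapping:
    return partition.assignment if isinstance(partition, Partition) else dict(partition)


def map_equation(net, partition, weighted: bool = False) -> float:
    """Two-level map equation L(M) in bits per step for an undirected graph.

    Visit rates are degree-proportional (strength-proportional when
    ``weighted``); exit rates come from inter-module edge mass; logarithms
    are base 2. Degree-zero nodes are excluded from the visit rates.
    """
    g = _graph(net)
    assign = _assignment(partition)
    missing = [n for n in g.nodes if n not in assign]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    wkey = "weight" if weighted else None
    strength = dict(g.degree(weight=wkey))
    total = sum(strength.values())
    if total == 0:
        return 0.0
    p_node = {n: s / total for n, s in strength.items() if s > 0}
    p_mod: Dict[int, float] = {}
    cut: Dict[int, float] = {}
    for n, p in p_node.items():
        m = assign[n]
        p_mod[m] = p_mod.get(m, 0.0) + p
    for u, v, data in g.edges(data=True):
        if u == v:
            continue
        mu, mv = assign[u], assign[v]
        if mu != mv:
            w = data.get("weight", 1.0) if weighted else 1.0
            cut[mu] = cut.get(mu, 0.0) + w / total
            cut[mv] = cut.get(mv, 0.0) + w / total
    q_total = sum(cut.values())
    L = _plogp(q_total)
    L -= 2 * sum(_plogp(q) for q in cut.values())
    L -= sum(_plogp(p) for p in p_node.values())
    L += sum(_plogp(p_mod[m] + cut.get(m, 0.0)) for m in p_mod)
    return L


class _MapEqState:
    """Mutable module aggregates supporting O(deg) move evaluation."""

    def __init__(self, adj, strength, total):
        # edge weights kept in visit-rate units (w / total degree mass)
        self.adj = [[(v, w / total) for v, w in a] for a in adj]
        self.p = [s / total for s in strength]
        n = len(strength)
        self.labels = list(range(n))
        self.p_mod = list(self.p)
        self.cut = [s / total for s in strength]  # singleton cut = strength
        self.q = sum(self.cut)
        self.L = self._full_L()

    def _terms(self, qm, pm):
        return -2 * _plogp(qm) + _plogp(pm + qm)

    def _full_L(self):
        L = _plogp(self.q)
        for m in set(self.labels):
            pm = self.p_mod[m]
            qm = self.cut[m]
            if pm > 0 or qm > 0:
                L += self._terms(qm, pm)
        L -= sum(_plogp(p) for p in self.p)
        return L

    def neighbor_weights(self, u):
        """Weight from u to each adjacent module (excluding self-loops)."""
        out: Dict[int, float] = {}
        for v, w in self.adj[u]:
            if v == u:
                continue
            m = self.labels[v]
            out[m] = out.get(m, 0.0) + w
        return out

    def delta_move(self, u, target, w_to, s_u):
        """Exact change in L for moving node u to module ``target``."""
        a = self.labels[u]
        if target == a:
            return 0.0
        e_ua = w_to.get(a, 0.0)
        e_ub = w_to.get(target, 0.0)
        pa, qa = self.p_mod[a], self.cut[a]
        pb, qb = self.p_mod[target], self.cut[target]
        qa2 = qa - s_u + 2 * e_ua
        qb2 = qb + s_u - 2 * e_ub
        pa2 = pa - self.p[u]
        pb2 = pb + self.p[u]
        q2 = self.q - qa - qb + qa2 + qb2
        d = _plogp(q2) - _plogp(self.q)
        d += self._terms(qa2, pa2) - self._terms(qa, pa)
        d += self._terms(qb2, pb2) - self._terms(qb, pb)
        return d

    def apply_move(self, u, target, w_to, s_u):
        a = self.labels[u]
        e_ua = w_to.get(a, 0.0)
        e_ub = w_to.get(target, 0.0)
        qa2 = self.cut[a] - s_u + 2 * e_ua
        qb2 = self.cut[target] + s_u - 2 * e_ub
        self.q += qa2 + qb2 - self.cut[a] - self.cut[target]
        self.cut[a] = qa2
        self.cut[target] = qb2
        self.p_mod[a] -= self.p[u]
        self.p_mod[target] += self.p[u]
        self.labels[u] = target
        self.L = self._full_L()


def _greedy_trial(state: _MapEqState, strength_norm, order, rng) -> None:
    """One restart: node-move passes alternated with module-merge passes."""
    n = len(state.labels)
    improved_any = True
    while improved_any:
        improved_any = False
        # local node moves until a full pass makes no improvement
        moving = True
        while moving:
            moving = False
            for u in order:
                s_u = strength_norm[u]
                if s_u == 0:
                    continue
                w_to = state.neighbor_weights(u)
                best_d, best_m = -_EPS, None
                for m in w_to:
                    d = state.delta_move(u, m, w_to, s_u)
                    if d < best_d:
                        best_d, best_m = d, m
                if best_m is not None:
                    state.apply_move(u, best_m, w_to, s_u)
                    moving = True
                    improved_any = True
        # merge adjacent modules while any merge lowers L
        merged = True
        while merged:
            merged = False
            inter: Dict[tuple, float] = {}
            for u in range(n):
                for v, w in state.adj[u]:
                    if v <= u:
                        continue
                    a, b = state.labels[u], state.labels[v]
                    if a != b:
                        key = (a, b) if a < b else (b, a)
                        inter[key] = inter.get(key, 0.0) + w
            best_d, best_pair = -_EPS, None
            for (a, b), w_ab in inter.items():
                pa, qa = state.p_mod[a], state.cut[a]
                pb, qb = state.p_mod[b], state.cut[b]
                qm = qa + qb - 2 * w_ab
                q2 = state.q - qa - qb + qm
                d = _plogp(q2) - _plogp(state.q)
                d += state._terms(qm, pa + pb)
                d -= state._terms(qa, pa) + state._terms(qb, pb)
                if d < best_d:
                    best_d, best_pair = d, (a, b)
            if best_pair is not None:
                a, b = best_pair
                for u in range(n):
                    if state.labels[u] == b:
                        state.labels[u] = a
                state.p_mod[a] += state.p_mod[b]
                pa_cut = state.cut[a] + state.cut[b] - 2 * inter[best_pair]
                state.q += pa_cut - state.cut[a] - state.cut[b]
                state.cut[a] = pa_cut
                state.p_mod[b] = 0.0
                state.cut[b] = 0.0
                state.L = state._full_L()
                merged = True
                improved_any = True


def infomap_partition(net, n_trials: int = 10, seed: int = 0,
                      weighted: bool = False) -> Partition:
    """Two-level map-equation partition by greedy descent with restarts.

    Each trial starts from singleton modules and alternates local node
    moves (scored by the exact change in L) with module merges until no
    step lowers L; the single-module and connected-component partitions are
    always evaluated as deterministic baselines; the lowest-L labeling over
    all candidates is returned. Deterministic given ``seed`` and
    ``n_trials``.
    """
    g = _graph(net)
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    idx = {node: i for i, node in enumerate(nodes)}
    wkey = "weight" if weighted else None
    adj = [[] for _ in range(n)]
    for u, v, data in g.edges(data=True):
        if u == v:
            continue
        w = data.get("weight", 1.0) if weighted else 1.0
        adj[idx[u]].append((idx[v], w))
        adj[idx[v]].append((idx[u], w))
    strength = [sum(w for _, w in a) for a in adj]
    total = sum(strength)

    def score(labels):
        return map_equation(g, {nodes[i]: labels[i] for i in range(n)},
                            weighted=weighted)

    candidates = []
    # deterministic baselines: all-in-one and connected components
    candidates.append([0] * n)
    comp_labels = [0] * n
    for ci, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_labels[idx[node]] = ci
    candidates.append(comp_labels)

    rng = np.random.default_rng(seed)
    if total > 0:
        strength_norm = [s / total for s in strength]
        for _ in range(max(1, n_trials)):
            state = _MapEqState(adj, strength, total)
            order = list(rng.permutation(n))
            _greedy_trial(state, strength_norm, order, rng)
            candidates.append(list(state.labels))

    best_labels, best_L = None, math.inf
    for labels in candidates:
        L = score(labels)
        if L < best_L - _EPS:
            best_L, best_labels = L, labels

    # contiguous module ids ordered by decreasing size (ties: smallest node id)
    groups: Dict[int, list] = {}
    for i, lab in enumerate(best_labels):
        groups.setdefault(lab, []).append(i)
    ordered = sorted(groups.values(), key=lambda ix: (-len(ix), str(nodes[ix[0]])))
    assignment = {}
    for new_id, members in enumerate(ordered):
        for i in members:
            assignment[nodes[i]] = new_id

    q_global = newman_modularity(g, assignment, weighted=weighted) \
        if g.number_of_edges() else 0.0
    q_per = per_module_q(g, assignment, weighted=weighted) \
        if g.number_of_edges() else {}
    return Partition(
        assignment=assignment,
        n_modules=len(ordered),
        map_equation_bits=best_L,
        modularity_q=q_global,
        per_module_q=q_per,
        trials=n_trials,
        seed=seed,
    )


def newman_modularity(net, partition, weighted: bool = False) -> float:
    """Newman modularity Q = sum_c [e_c/m - (d_c/2m)^2]."""
    return sum(per_module_q(net, partition, weighted=weighted).values())


def per_module_q(net, partition, weighted: bool = False) -> Dict[int, float]:
    """Per-module contributions to Q; they sum exactly to the global value."""
    g = _graph(net)
    assign = _assignment(partition)
    wkey = "weight" if weighted else None
    m2 = sum(d for _, d in g.degree(weight=wkey))  # 2m
    if m2 == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    within: Dict[int, float] = {}
    deg_sum: Dict[int, float] = {}
    for node, d in g.degree(weight=wkey):
        c = assign[node]
        deg_sum[c] = deg_sum.get(c, 0.0) + d
        within.setdefault(c, 0.0)
    for u, v, data in g.edges(data=True):
        w = data.get("weight", 1.0) if weighted else 1.0
        if assign[u] == assign[v]:
            within[assign[u]] += w
    m = m2 / 2.0
    return {c: within[c] / m - (deg_sum[c] / m2) ** 2 for c in deg_sum}


def nmi(partition_a, partition_b, normalization: str = "arithmetic") -> float:
    """Normalized mutual information between two node partitions.

    Computed on the intersection of the two node sets (plug-in estimate on
    the label contingency table); by default normalized by the arithmetic
    mean of the label entropies.
    """
    pa, pb = _assignment(partition_a), _assignment(partition_b)
    common = sorted(set(pa) & set(pb), key=str)
    if not common:
        raise ValueError("partitions share no nodes")
    la = pd.Categorical([pa[n] for n in common]).codes
    lb = pd.Categorical([pb[n] for n in common]).codes
    n = len(common)
    cont = pd.crosstab(la, lb).to_numpy(dtype=float) / n
    pr_a = cont.sum(axis=1)
    pr_b = cont.sum(axis=0)
    ha = -sum(_xlogx(p) for p in pr_a)
    hb = -sum(_xlogx(p) for p in pr_b)
    mask = cont > 0
    info = float(np.sum(cont[mask] * np.log(cont[mask] / np.outer(pr_a, pr_b)[mask])))
    if normalization == "arithmetic":
        denom = (ha + hb) / 2.0
    elif normalization == "max":
        denom = max(ha, hb)
    elif normalization == "min":
        denom = min(ha, hb)
    elif normalization == "joint":
        denom = -float(np.sum(cont[mask] * np.log(cont[mask])))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom == 0:
        # both partitions trivial: identical iff single shared label each
        return 1.0
    val = info / denom
    if abs(val) < 1e-12:
        return 0.0
    return max(0.0, min(1.0, val))


def _xlogx(p: float) -> float:
    return p * math.log(p) if p > 0 else 0.0


def membership_similarity(
    partition_a,
    partition_b,
    thresholds: Sequence[float] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5),
) -> ModuleSimilarity:
    """Jaccard similarity matrix between the gene modules of two partitions.

    The preservation summary counts greedily matched one-to-one module pairs
    (highest Jaccard first, each module used once) whose similarity reaches
    each threshold.
    """
    mods_a = _modules_by_size(partition_a)
    mods_b = _modules_by_size(partition_b)
    mat = pd.DataFrame(
        [[_jaccard(sa, sb) for sb in mods_b.values()] for sa in mods_a.values()],
        index=list(mods_a), columns=list(mods_b), dtype=float,
    )
    pairs = sorted(
        ((a, b, mat.loc[a, b]) for a in mat.index for b in mat.columns),
        key=lambda t: (-t[2], str(t[0]), str(t[1])),
    )
    used_a, used_b, matches = set(), set(), []
    for a, b, j in pairs:
        if a in used_a or b in used_b or j <= 0:
            continue
        used_a.add(a)
        used_b.add(b)
        matches.append((a, b, j))
    best = pd.Series(0.0, index=mat.index)
    for a, _, j in matches:
        best.loc[a] = j
    counts = {t: int(sum(1 for _, _, j in matches if j >= t - 1e-12))
              for t in thresholds}
    return ModuleSimilarity(matrix=mat, matches=matches,
                            preservation_counts=counts,
                            best_match_jaccard=best)


def _modules_by_size(partition) -> Dict:
    assign = _assignment(partition)
    groups: Dict = {}
    for node, m in assign.items():
        groups.setdefault(m, set()).add(node)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), str(kv[0])))
    return dict(ordered)


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0
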