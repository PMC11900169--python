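"""Two-condition synthetic RNA-seq counts with planted co-expression structure.

The generator emulates the statistical structure the pipeline is built to
detect: a shared gene universe; negative-binomial count marginals; modules
of co-expressed genes induced by a Gaussian copula (one shared latent factor
per module, so within-module latent correlation is exactly the configured
rho); a controlled cross-condition rearrangement in which a fixed fraction
of each module's genes is reassigned round-robin to the other modules in
condition B; and a handful of condition-B hub genes that load on half of the
module factors at once. Because the reassignment is deterministic
round-robin, the expected best-match Jaccard between the two planted
partitions is available in closed form for equal module sizes s and r
reassigned genes per module: (s - r) / (s + r).

The copula + negative-binomial construction gives monotone but non-linear
gene-gene dependence, exercising mutual information's advantage over linear
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import nbinom, norm

from .enrichment import AnnotationSet
from .preprocess import CountMatrix

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "make_design",
    "generate_two_condition_counts",
    "generate_annotations",
    "expected_best_match_jaccard",
]

BACKGROUND = -1  # module label for genes outside every planted module


class DesignError(ValueError):
    """Invalid generator design; message names the offending field."""


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the two-condition planted-structure generator.

    Defaults follow the benchmark conditions used throughout the test
    suite: 2,000 genes, ten modules of 50 genes, latent within-module
    correlation 0.8, 150 samples per condition, 20% of each module's genes
    reassigned in condition B, and five condition-B hub genes.
    """

    n_genes: int = 2000
    n_samples_a: int = 150
    n_samples_b: int = 150
    modules_a: Tuple[Tuple[int, ...], ...] = ()
    rearrangement_fraction: float = 0.2
    within_module_rho: float = 0.8
    n_hubs_b: int = 5
    nb_mean_log_range: Tuple[float, float] = (1.0, 5.0)
    nb_dispersion: float = 0.2
    library_size_range: Tuple[float, float] = (8e5, 1.2e6)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise DesignError("n_genes must be positive")
        if self.n_samples_a < 4 or self.n_samples_b < 4:
            raise DesignError("n_samples_a/n_samples_b must be >= 4")
        if not 0.0 <= self.rearrangement_fraction <= 1.0:
            raise DesignError("rearrangement_fraction must lie in [0, 1]")
        if not 0.0 <= self.within_module_rho < 1.0:
            raise DesignError("within_module_rho must lie in [0, 1)")
        if self.n_hubs_b < 0:
            raise DesignError("n_hubs_b must be non-negative")
        if self.nb_dispersion <= 0:
            raise DesignError("nb_dispersion must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise DesignError("library_size_range must be positive and ordered")
        seen: set = set()
        for mod in self.modules_a:
            for g in mod:
                if g in seen:
                    raise DesignError("modules_a sets must be pairwise disjoint")
                if not 0 <= g < self.n_genes:
                    raise DesignError("modules_a indices must lie in the gene universe")
                seen.add(g)


@dataclass
class GroundTruth:
    """Planted gene -> module maps and hub set for both conditions."""

    partition_a: Dict[str, int]
    partition_b: Dict[str, int]
    hub_genes_b: set
    generator_params: SyntheticDesign

    def modules_a(self) -> Dict[int, set]:
        return _group(self.partition_a)

    def modules_b(self) -> Dict[int, set]:
        return _group(self.partition_b)


def _group(partition: Dict[str, int]) -> Dict[int, set]:
    out: Dict[int, set] = {}
    for g, m in partition.items():
        if m != BACKGROUND:
            out.setdefault(m, set()).add(g)
    return out


def make_design(
    n_genes: int = 2000,
    n_modules: int = 10,
    module_size: int = 50,
    n_samples: int = 150,
    rearrangement_fraction: float = 0.2,
    within_module_rho: float = 0.8,
    n_hubs_b: int = 5,
    seed: int = 0,
    **kwargs,
) -> SyntheticDesign:
    """Convenience constructor with contiguous equal-size modules."""
    if n_modules * module_size > n_genes:
        raise DesignError("modules exceed the gene universe")
    modules = tuple(
        tuple(range(j * module_size, (j + 1) * module_size))
        for j in range(n_modules)
    )
    design = SyntheticDesign(
        n_genes=n_genes,
        n_samples_a=n_samples,
        n_samples_b=n_samples,
        modules_a=modules,
        rearrangement_fraction=rearrangement_fraction,
        within_module_rho=within_module_rho,
        n_hubs_b=n_hubs_b,
        seed=seed,
        **kwargs,
    )
    design.validate()
    return design


def expected_best_match_jaccard(module_size: int, rearrangement_fraction: float) -> float:
    """Closed-form best-match Jaccard under round-robin reassignment.

    With equal module sizes s and r = floor(f * s) genes moved out of (and,
    by symmetry, into) each module, J(m_a, m_b) = (s - r) / (s + r).
    """
    r = math.floor(rearrangement_fraction * module_size)
    return (module_size - r) / (module_size + r)


def _rearranged_partition(
    design: SyntheticDesign, rng: np.random.Generator
) -> Tuple[Dict[int, int], Dict[int, int]]:
    """Gene-index -> module maps for both conditions (round-robin moves)."""
    part_a = {g: BACKGROUND for g in range(design.n_genes)}
    for j, mod in enumerate(design.modules_a):
        for g in mod:
            part_a[g] = j
    part_b = dict(part_a)
    n_mod = len(design.modules_a)
    if n_mod >= 2 and design.rearrangement_fraction > 0:
        for j, mod in enumerate(design.modules_a):
            r = math.floor(design.rearrangement_fraction * len(mod))
            movers = rng.choice(np.asarray(sorted(mod)), size=r, replace=False)
            # deterministic round-robin over the other modules, starting at j+1
            for i, g in enumerate(sorted(movers)):
                part_b[int(g)] = (j + 1 + i % (n_mod - 1)) % n_mod
    return part_a, part_b


def _latents(
    partition: Dict[int, int],
    n_modules: int,
    n_samples: int,
    rho: float,
    hub_loadings: Optional[Dict[int, Sequence[int]]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian-copula latents: shared module factor + idiosyncratic noise."""
    n_genes = len(partition)
    factors = rng.standard_normal((n_modules, n_samples)) if n_modules else \
        np.empty((0, n_samples))
    z = rng.standard_normal((n_genes, n_samples)) * math.sqrt(1.0 - rho)
    for g in range(n_genes):
        m = partition[g]
        if m != BACKGROUND:
            z[g] += math.sqrt(rho) * factors[m]
        elif hub_loadings and g in hub_loadings:
            load = hub_loadings[g]
            z[g] += math.sqrt(rho / len(load)) * factors[list(load)].sum(axis=0)
        else:
            # background gene: independent noise, unit total latent variance
            z[g] += math.sqrt(rho) * rng.standard_normal(n_samples)
    return z


def generate_two_condition_counts(
    design: SyntheticDesign,
) -> Tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Generate count matrices for conditions A and B plus ground truth.

    Per module, a shared standard-normal factor plus idiosyncratic noise
    gives latent within-module correlation ``within_module_rho``; latents
    are mapped through the negative-binomial quantile function with a
    gene-specific mean drawn log-uniformly from ``nb_mean_log_range``
    (shared across conditions) scaled by per-sample relative depth, and a
    common dispersion. Condition B uses the rearranged partition; its hub
    genes additionally load on ceil(n_modules / 2) module factors.
    Deterministic given the design seed.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n_mod = len(design.modules_a)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(design.n_genes)], name="gene")

    part_a_idx, part_b_idx = _rearranged_partition(design, rng)

    # gene-level NB parameters, shared between conditions
    lo, hi = design.nb_mean_log_range
    base_mean = np.exp(rng.uniform(lo, hi, size=design.n_genes))
    size = 1.0 / design.nb_dispersion

    # hubs: background genes loading on ceil(n_modules/2) factors in B only
    background = np.array([g for g, m in part_a_idx.items() if m == BACKGROUND])
    n_hubs = min(design.n_hubs_b, background.size)
    hub_idx = rng.choice(background, size=n_hubs, replace=False) if n_hubs else \
        np.array([], dtype=int)
    n_load = math.ceil(n_mod / 2) if n_mod else 0
    hub_loadings = {
        int(g): tuple(sorted(rng.choice(n_mod, size=n_load, replace=False)))
        for g in hub_idx
    } if n_load else {}

    def _condition(partition, n_samples, hubs):
        z = _latents(partition, n_mod, n_samples, design.within_module_rho,
                     hubs, rng)
        libs = rng.uniform(*design.library_size_range, size=n_samples)
        depth = libs / libs.mean()
        mu = base_mean[:, None] * depth[None, :]
        u = np.clip(norm.cdf(z), 1e-12, 1.0 - 1e-12)
        counts = nbinom.ppf(u, size, size / (size + mu)).astype(np.int64)
        return counts

    counts_a = _condition(part_a_idx, design.n_samples_a, None)
    counts_b = _condition(part_b_idx, design.n_samples_b, hub_loadings)

    samples_a = pd.Index([f"A{i:03d}" for i in range(design.n_samples_a)])
    samples_b = pd.Index([f"B{i:03d}" for i in range(design.n_samples_b)])
    mat_a = CountMatrix(
        values=pd.DataFrame(counts_a, index=gene_ids, columns=samples_a),
        sample_condition=pd.Series("A", index=samples_a),
        provenance=[{"step": "simulate", "condition": "A", "seed": design.seed}],
    )
    mat_b = CountMatrix(
        values=pd.DataFrame(counts_b, index=gene_ids, columns=samples_b),
        sample_condition=pd.Series("B", index=samples_b),
        provenance=[{"step": "simulate", "condition": "B", "seed": design.seed}],
    )
    truth = GroundTruth(
        partition_a={gene_ids[g]: m for g, m in part_a_idx.items()},
        partition_b={gene_ids[g]: m for g, m in part_b_idx.items()},
        hub_genes_b={gene_ids[int(g)] for g in hub_idx},
        generator_params=design,
    )
    return mat_a, mat_b, truth


def generate_annotations(
    truth: GroundTruth,
    n_decoy_terms: int = 0,
    coverage: float = 1.0,
    seed: int = 0,
) -> AnnotationSet:
    """Term -> gene annotations aligned with the planted condition-A modules.

    One "true" term per planted module contains a ``coverage``-fraction
    random subset of its genes; ``n_decoy_terms`` additional terms hold
    random genes with a matched size distribution. Every term has at least
    two genes; the universe is the whole gene set.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    modules = truth.modules_a()
    if not modules or any(len(m) == 0 for m in modules.values()):
        raise ValueError("ground truth has no non-empty planted modules")
    rng = np.random.default_rng(seed)
    universe = sorted(truth.partition_a)
    terms: Dict[str, set] = {}
    descriptions: Dict[str, str] = {}
    sizes: List[int] = []
    for m in sorted(modules):
        genes = sorted(modules[m])
        k = max(2, int(round(coverage * len(genes))))
        if coverage >= 1.0:
            subset = set(genes)
        else:
            subset = set(rng.choice(genes, size=min(k, len(genes)), replace=False))
        term = f"TRUE_MODULE_{m:03d}"
        terms[term] = subset
        descriptions[term] = f"planted co-expression module {m}"
        sizes.append(len(subset))
    for d in range(n_decoy_terms):
        size = int(sizes[int(rng.integers(len(sizes)))])
        term = f"DECOY_{d:03d}"
        terms[term] = set(rng.choice(universe, size=max(2, size), replace=False))
        descriptions[term] = "random decoy term"
    return AnnotationSet(terms=terms, descriptions=descriptions,
                         universe=set(universe))
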