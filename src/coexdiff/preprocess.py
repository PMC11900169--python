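"""Count-matrix preprocessing: low-count filtering, TMM normalization, stratification.

The pipeline starts from a gene x sample matrix of integer RNA-seq counts.
Before network inference, genes with negligible expression are removed by a
counts-per-million (CPM) rule, between-sample composition differences are
corrected with trimmed-mean-of-M-values (TMM) scaling factors, and the
normalized matrix is split into one expression matrix per phenotype group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "cpm_filter",
    "tmm_factors",
    "normalize",
    "stratify",
]


class PreprocessError(ValueError):
    """Raised for invalid preprocessing inputs (offending field in the message)."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with optional per-sample condition labels.

    Parameters
    ----------
    values
        DataFrame of non-negative integer counts; index = gene ids,
        columns = sample ids, both unique.
    sample_condition
        Optional Series mapping sample id -> condition label.
    gene_lengths
        Optional Series of gene lengths in bp (positive), indexed by gene id.
    provenance
        List of dicts recording applied processing steps.
    """

    values: pd.DataFrame
    sample_condition: Optional[pd.Series] = None
    gene_lengths: Optional[pd.Series] = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise PreprocessError("duplicate gene ids in count matrix")
        if self.values.columns.has_duplicates:
            raise PreprocessError("duplicate sample ids in count matrix")
        if (np.asarray(self.values) < 0).any():
            raise PreprocessError("negative counts in count matrix")
        if self.gene_lengths is not None:
            if (self.gene_lengths.reindex(self.values.index) <= 0).any():
                raise PreprocessError("gene_lengths must be positive for every gene")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)


@dataclass
class NormalizedMatrix:
    """CPM-scale expression values after TMM (and optional length) normalization."""

    values: pd.DataFrame
    normalization_factors: pd.Series
    sample_condition: Optional[pd.Series] = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        f = np.asarray(self.normalization_factors, dtype=float)
        if (f <= 0).any():
            raise PreprocessError("normalization_factors must be positive")
        gmean = float(np.exp(np.mean(np.log(f))))
        if abs(gmean - 1.0) > 1e-9:
            raise PreprocessError(
                f"normalization_factors must have geometric mean 1 (got {gmean!r})"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def cpm_filter(
    counts: CountMatrix,
    cpm_threshold: float = 1.0,
    min_samples_over_cpm: Optional[int] = None,
) -> CountMatrix:
    """Remove genes with low counts-per-million.

    By default a gene is kept when its *mean* CPM across samples is at least
    ``cpm_threshold``. Setting ``min_samples_over_cpm`` switches to the
    per-sample variant: keep genes whose CPM exceeds the threshold in at
    least that many samples.
    """
    lib = counts.library_sizes.to_numpy(dtype=float)
    if not (lib > 0).any():
        raise PreprocessError("all library sizes are zero")
    safe_lib = np.where(lib > 0, lib, np.nan)
    cpm = counts.values.to_numpy(dtype=float) / safe_lib * 1e6
    if min_samples_over_cpm is None:
        keep = np.nanmean(cpm, axis=1) >= cpm_threshold
    else:
        keep = np.nansum(cpm >= cpm_threshold, axis=1) >= min_samples_over_cpm
    n_removed = int((~keep).sum())
    if not keep.any():
        raise PreprocessError(
            f"cpm_filter removed all {len(keep)} genes at threshold {cpm_threshold}"
        )
    out = CountMatrix(
        values=counts.values.loc[keep],
        sample_condition=counts.sample_condition,
        gene_lengths=(
            counts.gene_lengths.loc[counts.values.index[keep]]
            if counts.gene_lengths is not None
            else None
        ),
        provenance=counts.provenance
        + [
            {
                "step": "cpm_filter",
                "cpm_threshold": cpm_threshold,
                "min_samples_over_cpm": min_samples_over_cpm,
                "n_removed": n_removed,
                "n_kept": int(keep.sum()),
            }
        ],
    )
    return out


def _choose_reference(values: np.ndarray) -> int:
    """Sample whose upper-quartile CPM is closest to the mean of upper quartiles."""
    lib = values.sum(axis=0)
    cpm = values / lib * 1e6
    uq = np.percentile(cpm, 75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    counts: CountMatrix,
    ref_sample: Optional[str] = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Robinson-Oshlack TMM scaling factors, re-centered to geometric mean 1.

    For each sample against the reference, log2 expression ratios (M) and
    mean log2 abundances (A) are computed on genes positive in both samples,
    symmetric rank trimming is applied (``trim_m`` on M, ``trim_a`` on A),
    and the factor is two to the power of the inverse-asymptotic-variance
    weighted mean of the surviving M values.
    """
    values = counts.values.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    if ref_sample is None:
        ref_idx = _choose_reference(values)
    else:
        ref_idx = int(counts.sample_ids.get_loc(ref_sample))
    yr = values[:, ref_idx]
    nr = lib[ref_idx]

    log_factors = np.zeros(values.shape[1])
    for s in range(values.shape[1]):
        if s == ref_idx:
            continue
        ys, ns = values[:, s], lib[s]
        pos = (ys > 0) & (yr > 0)
        if not pos.any():
            raise PreprocessError(
                f"sample {counts.sample_ids[s]!r} shares no positive genes "
                "with the reference"
            )
        y1, y2 = ys[pos], yr[pos]
        m = np.log2((y1 / ns) / (y2 / nr))
        a = 0.5 * np.log2((y1 / ns) * (y2 / nr))
        w = (ns - y1) / (ns * y1) + (nr - y2) / (nr * y2)
        n = m.size
        # symmetric trimming by rank, matching the original TMM description
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m)
        ra = rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any() and w[keep].sum() > 0:
            log_factors[s] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        else:
            log_factors[s] = 0.0
    factors = 2.0 ** (log_factors - log_factors.mean())
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def normalize(
    counts: CountMatrix,
    factors: pd.Series,
    use_lengths: bool = False,
) -> NormalizedMatrix:
    """CPM normalization with TMM effective library sizes.

    value = count / (library_size * factor) * 1e6, further divided by
    gene length in kb when ``use_lengths`` is set.
    """
    factors = factors.reindex(counts.sample_ids)
    lib = counts.library_sizes.to_numpy(dtype=float)
    eff = lib * factors.to_numpy(dtype=float)
    vals = counts.values.to_numpy(dtype=float) / eff * 1e6
    steps = list(counts.provenance) + [
        {"step": "normalize", "use_lengths": bool(use_lengths)}
    ]
    if use_lengths:
        if counts.gene_lengths is None:
            raise PreprocessError("use_lengths requested but gene_lengths missing")
        kb = counts.gene_lengths.reindex(counts.gene_ids).to_numpy(dtype=float) / 1e3
        vals = vals / kb[:, None]
    return NormalizedMatrix(
        values=pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        normalization_factors=pd.Series(
            factors.to_numpy()
            / np.exp(np.mean(np.log(factors.to_numpy()))),  # keep gmean exactly 1
            index=counts.sample_ids,
            name="tmm_factor",
        ),
        sample_condition=counts.sample_condition,
        provenance=steps,
    )


def stratify(matrix, condition_labels: Optional[pd.Series] = None) -> dict:
    """Split a count or normalized matrix into per-condition matrices.

    Every sample must carry a condition label; gene rows are identical across
    the returned matrices and the sample sets partition the input columns.
    """
    labels = condition_labels if condition_labels is not None else matrix.sample_condition
    if labels is None:
        raise PreprocessError("no condition labels available for stratification")
    labels = pd.Series(labels).reindex(matrix.sample_ids)
    if labels.isna().any():
        missing = list(matrix.sample_ids[labels.isna()])
        raise PreprocessError(f"samples without condition label: {missing}")
    out = {}
    for cond in pd.unique(labels):
        cols = matrix.sample_ids[labels.to_numpy() == cond]
        if isinstance(matrix, CountMatrix):
            out[cond] = CountMatrix(
                values=matrix.values[cols],
                sample_condition=labels[cols],
                gene_lengths=matrix.gene_lengths,
                provenance=matrix.provenance
                + [{"step": "stratify", "condition": str(cond)}],
            )
        else:
            out[cond] = NormalizedMatrix(
                values=matrix.values[cols],
                normalization_factors=_recenter(matrix.normalization_factors[cols]),
                sample_condition=labels[cols],
                provenance=matrix.provenance
                + [{"step": "stratify", "condition": str(cond)}],
            )
    return out


def _recenter(factors: pd.Series) -> pd.Series:
    f = factors.to_numpy(dtype=float)
    return pd.Series(f / np.exp(np.mean(np.log(f))), index=factors.index,
                     name=factors.name)
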