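"""Sample selection, gene filtering and TMM/CPM normalization.

The pipeline mirrors the standard bulk RNA-seq recipe: keep tissues with
enough donors, drop noise-level genes (at most ``max_raw`` counts in every
sample), compute trimmed-mean-of-M-values (TMM) scaling factors, and
convert to counts per million on the effective (factor-adjusted) library
sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import CountMatrix, SampleMeta, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TmmFactors:
    """Per-sample TMM normalization factors (geometric mean 1)."""

    factors: pd.Series  # index: sample_id
    reference_sample: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("TMM factors must be positive")


@dataclass
class CpmMatrix:
    """Counts per million for one tissue (or one pooled sample set)."""

    cpm: pd.DataFrame  # genes x samples, non-negative reals
    tissue: str
    factors: TmmFactors | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cpm.columns)

    def subset_samples(self, sample_ids) -> "CpmMatrix":
        return CpmMatrix(self.cpm.loc[:, list(sample_ids)], self.tissue, self.factors)


def select_tissues(
    meta: SampleMeta,
    min_samples: int = 10,
    death_cause_filter: str | None = None,
) -> list[tuple[str, list[str]]]:
    """Tissues with at least ``min_samples`` donors, with their sample ids.

    With ``death_cause_filter`` set, samples whose recorded cause of death
    differs are dropped before counting — used with post-mortem cohorts to
    keep only trauma donors, whose tissue is the most reliable healthy
    proxy. Tissue order is lexicographic, sample order as in the metadata.
    """
    table = meta.table
    if death_cause_filter is not None:
        table = table[table["death_cause"] == death_cause_filter]
    out = []
    for tissue in sorted(table["tissue"].unique()):
        samples = list(table.index[table["tissue"] == tissue])
        if len(samples) >= min_samples:
            out.append((tissue, samples))
    return out


def filter_low_count_genes(counts: CountMatrix, max_raw: int = 10) -> CountMatrix:
    """Drop genes with at most ``max_raw`` raw counts in every sample."""
    keep = (counts.counts > max_raw).any(axis=1)
    if not keep.any():
        logger.warning("all %d genes fall below the raw-count filter", counts.n_genes)
    return CountMatrix(counts.counts.loc[keep])


def _quantile_type5(x: np.ndarray, p: float) -> float:
    # R's quantile(type=5), used when picking the TMM reference column
    n = len(x)
    xs = np.sort(x)
    h = n * p + 0.5
    lo = int(np.clip(np.floor(h - 0.5), 0, n - 1))
    hi = int(np.clip(np.ceil(h - 0.5), 0, n - 1))
    g = h - 0.5 - np.floor(h - 0.5)
    return xs[lo] * (1 - g) + xs[hi] * g


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    weighted: bool,
) -> float:
    """Two-sample TMM factor: trimmed, precision-weighted mean of M-values."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2
        v = (lib_obs - obs) / lib_obs / obs + (lib_ref - ref) / lib_ref / ref
    finite = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> TmmFactors:
    """TMM normalization factors against an automatically chosen reference.

    The reference is the sample whose 75th-percentile count fraction is
    closest to the mean of those fractions. For each sample, genes absent
    from either the sample or the reference are excluded; M-values are
    trimmed two-sided by ``logratio_trim`` and A-values by ``sum_trim``;
    the factor is the (inverse-variance weighted) mean M on the kept
    genes; factors are rescaled to geometric mean 1.
    """
    if counts.n_samples < 2:
        raise ValidationError("TMM needs at least two samples")
    mat = counts.counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.sample_ids[int(np.argmin(lib))]
        raise ValidationError(f"sample {bad!r} has zero library size")
    f75 = np.array(
        [_quantile_type5(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])]
    )
    if np.median(f75) < 1e-20:
        ref_idx = int(np.argmax(np.sqrt(mat).sum(axis=0)))  # near-empty libraries
    else:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = mat[:, ref_idx]
    factors = np.array(
        [
            _tmm_pair(mat[:, j], ref, lib[j], lib[ref_idx], logratio_trim, sum_trim, weighted)
            for j in range(mat.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return TmmFactors(
        factors=pd.Series(factors, index=counts.sample_ids),
        reference_sample=counts.sample_ids[ref_idx],
    )


def to_cpm(
    counts: CountMatrix,
    factors: TmmFactors | None = None,
    tissue: str = "",
) -> CpmMatrix:
    """cpm(g, s) = count(g, s) / (library_size(s) * factor(s)) * 1e6."""
    lib = counts.library_sizes().astype(float)
    if factors is not None:
        missing = set(counts.sample_ids) - set(factors.factors.index)
        if missing:
            raise ValidationError(f"no TMM factor for sample(s): {sorted(missing)[:5]}")
        lib = lib * factors.factors.reindex(counts.sample_ids)
    cpm = counts.counts.div(lib, axis=1) * 1e6
    return CpmMatrix(cpm=cpm, tissue=tissue, factors=factors)


def expressed_mask(
    cpm: CpmMatrix, threshold: float, fraction: float = 0.8
) -> pd.Series:
    """Genes with cpm strictly above ``threshold`` in >= ceil(fraction*n) samples."""
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must be in (0, 1]")
    n = cpm.cpm.shape[1]
    needed = int(np.ceil(fraction * n))
    return (cpm.cpm > threshold).sum(axis=1) >= needed
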