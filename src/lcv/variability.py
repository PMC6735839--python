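"""Expression-variability measures: SD, CV, MAD, DM, EV and LCV.

The local measures (LCV, DM, EV) all start from the same construction:
genes of one tissue are sorted by their median expression, and each
gene's coefficient of variation (CV) is judged against genes of similar
expression level. LCV is the percentile rank of a gene's CV inside a
sliding window of the ``m`` genes closest to it on the expression scale
(0 = least variable in its window, 100 = most variable); DM is the
distance of the CV from the window median; EV is the ratio of the CV to
a smooth (local-regression) expectation given expression level.

Being a rank statistic, LCV is invariant to rescaling the expression
matrix and to any monotone transform applied uniformly to the CVs, which
is what frees it from the expression-level bias that plagues SD and CV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .datamodel import ValidationError, VariabilityParams, VariabilityTable
from .preprocess import CpmMatrix, expressed_mask

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-gene dispersion statistics


def gene_sd(values, ddof: int = 1) -> float:
    """Sample standard deviation (ddof=1 by default)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValidationError("sd needs >= 2 finite values")
    return float(np.std(x, ddof=ddof))


def gene_mad(values) -> float:
    """Median absolute deviation from the median (unscaled)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValidationError("mad needs >= 2 finite values")
    return float(np.median(np.abs(x - np.median(x))))


def gene_cv(values, ddof: int = 1) -> float:
    """Coefficient of variation: sd / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValidationError("cv needs >= 2 finite values")
    mean = x.mean()
    if mean == 0:
        raise ValidationError("cv undefined: mean is zero")
    return float(np.std(x, ddof=ddof) / mean)


# ---------------------------------------------------------------------------
# the sorted frame and windows


@dataclass
class SortedGeneFrame:
    """Genes of one tissue ordered by median expression, with their CVs.

    Ties in median expression are broken lexicographically by gene id so
    every downstream score is reproducible.
    """

    gene_ids: np.ndarray  # object array, frame order
    median_expression: np.ndarray
    cv: np.ndarray
    tissue: str = ""

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if n < 2:
            raise ValidationError("a frame needs at least 2 genes")
        if np.any(np.diff(self.median_expression) < 0):
            raise ValidationError("frame not sorted by median expression")
        if not np.all(np.isfinite(self.cv)):
            raise ValidationError("frame contains non-finite CVs")

    def __len__(self) -> int:
        return len(self.gene_ids)


def build_sorted_frame(
    cpm: CpmMatrix, mask: pd.Series | None = None, ddof: int = 1
) -> SortedGeneFrame:
    """Sort masked genes by median cpm and attach their CVs."""
    mat = cpm.cpm if mask is None else cpm.cpm.loc[mask.reindex(cpm.cpm.index, fill_value=False)]
    if mat.shape[0] < 2:
        raise ValidationError("fewer than 2 genes pass the expression mask")
    values = mat.to_numpy(dtype=float)
    medians = np.median(values, axis=1)
    means = values.mean(axis=1)
    if np.any(means == 0):
        raise ValidationError("zero-mean gene in frame; tighten the expression mask")
    cv = values.std(axis=1, ddof=ddof) / means
    order = np.lexsort((np.asarray(mat.index, dtype=object), medians))
    return SortedGeneFrame(
        gene_ids=np.asarray(mat.index, dtype=object)[order],
        median_expression=medians[order],
        cv=cv[order],
        tissue=cpm.tissue,
    )


def window_bounds(i: int, n: int, m: int) -> tuple[int, int]:
    """Half-open [start, end) of the size-``min(m, n)`` window centred on gene ``i``.

    Interior windows are centred; at the two ends of the expression scale
    the window is shifted inward so it still holds ``m`` adjacent genes.
    """
    if not 0 <= i < n:
        raise ValidationError(f"center {i} outside [0, {n})")
    if m < 2:
        raise ValidationError("window size must be >= 2")
    w = min(m, n)
    start = int(np.clip(i - (m - 1) // 2, 0, max(n - m, 0)))
    return start, start + w


def _effective_window(n: int, m: int) -> int:
    if n < 2:
        raise ValidationError("need at least 2 genes")
    if m > n:
        logger.warning("window %d exceeds frame size %d; using one global window", m, n)
    return min(m, n)


def lcv(frame: SortedGeneFrame, m: int = 500) -> pd.Series:
    """Local CV percentile per gene, in [0, 100].

    For gene ``i`` with window W (|W| = w): the CV of ``i`` gets its
    average fractional rank r among the window CVs (ties share the mean
    of their rank range) and LCV = 100 * (r - 1) / (w - 1), so the
    window's strict minimum scores 0, its strict maximum 100, and a
    completely tied window scores 50 everywhere.
    """
    w = _effective_window(len(frame), m)
    cv = frame.cv
    n = len(cv)
    scores = np.empty(n)
    window = np.sort(cv[:w])
    prev_start = 0
    for i in range(n):
        start, _ = window_bounds(i, n, m)
        while prev_start < start:
            # slide: drop cv[prev_start], add cv[prev_start + w]
            pos = np.searchsorted(window, cv[prev_start])
            window = np.delete(window, pos)
            new = cv[prev_start + w]
            window = np.insert(window, np.searchsorted(window, new), new)
            prev_start += 1
        lo = np.searchsorted(window, cv[i], side="left")
        hi = np.searchsorted(window, cv[i], side="right")
        rank = lo + (hi - lo + 1) / 2.0
        scores[i] = 100.0 * (rank - 1.0) / (w - 1.0)
    return pd.Series(scores, index=frame.gene_ids)


def dm(frame: SortedGeneFrame, m: int = 500) -> pd.Series:
    """Distance of each gene's CV from its window's median CV."""
    w = _effective_window(len(frame), m)
    cv = frame.cv
    n = len(cv)
    scores = np.empty(n)
    window = np.sort(cv[:w])
    prev_start = 0
    mid = (w - 1) // 2
    for i in range(n):
        start, _ = window_bounds(i, n, m)
        while prev_start < start:
            pos = np.searchsorted(window, cv[prev_start])
            window = np.delete(window, pos)
            new = cv[prev_start + w]
            window = np.insert(window, np.searchsorted(window, new), new)
            prev_start += 1
        median = window[mid] if w % 2 else 0.5 * (window[mid] + window[mid + 1])
        scores[i] = cv[i] - median
    return pd.Series(scores, index=frame.gene_ids)


def ev(frame: SortedGeneFrame, nn: float = 0.3) -> pd.Series:
    """Ratio of observed CV to its local-regression expectation.

    Fits a lowess of log(CV) on log(median expression) with a
    nearest-neighbor span of ``nn`` (fraction of genes per local fit);
    EV_i = cv_i / exp(fit_i), so genes sitting on the trend score 1 and
    genes twice as dispersed as expected score ~2.
    """
    if len(frame) < 10:
        raise ValidationError("EV needs at least 10 genes")
    if np.any(frame.cv <= 0):
        raise ValidationError("EV needs strictly positive CVs")
    if not (0 < nn <= 1):
        raise ValidationError("nn must be in (0, 1]")
    x = np.log(frame.median_expression)
    y = np.log(frame.cv)
    fitted = sm.nonparametric.lowess(
        y, x, frac=nn, it=3, return_sorted=False, is_sorted=True
    )
    return pd.Series(frame.cv / np.exp(fitted), index=frame.gene_ids)


# ---------------------------------------------------------------------------
# orchestration


def compute_measures(
    frame: SortedGeneFrame,
    measures: tuple[str, ...],
    params: VariabilityParams,
    cpm: CpmMatrix,
) -> pd.DataFrame:
    """Long-format scores for one tissue's frame."""
    per_gene = cpm.cpm.loc[list(frame.gene_ids)].to_numpy(dtype=float)
    columns: dict[str, np.ndarray] = {}
    for measure in measures:
        if measure == "CV":
            columns["CV"] = frame.cv
        elif measure == "SD":
            columns["SD"] = per_gene.std(axis=1, ddof=params.cv_ddof)
        elif measure == "MAD":
            med = np.median(per_gene, axis=1, keepdims=True)
            columns["MAD"] = np.median(np.abs(per_gene - med), axis=1)
        elif measure == "LCV":
            columns["LCV"] = lcv(frame, params.window_m).to_numpy()
        elif measure == "DM":
            columns["DM"] = dm(frame, params.window_m).to_numpy()
        elif measure == "EV":
            columns["EV"] = ev(frame, params.ev_nn).to_numpy()
        else:
            raise ValidationError(f"unknown measure {measure!r}")
    rows = []
    for measure, scores in columns.items():
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": frame.gene_ids,
                    "tissue": frame.tissue,
                    "measure": measure,
                    "score": scores,
                    "median_expression": frame.median_expression,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def compute_all(
    cpm_by_tissue: dict[str, CpmMatrix],
    params: VariabilityParams,
    measures: tuple[str, ...] = ("LCV",),
) -> VariabilityTable:
    """Run mask -> frame -> measures for every tissue; skip unusable tissues."""
    if not cpm_by_tissue:
        raise ValidationError("no tissues supplied")
    frames = []
    for tissue in sorted(cpm_by_tissue):
        cpm = cpm_by_tissue[tissue]
        mask = expressed_mask(cpm, params.cpm_threshold, params.expressed_fraction)
        if mask.sum() < 2:
            logger.warning("tissue %s: fewer than 2 genes pass the mask; skipped", tissue)
            continue
        frame = build_sorted_frame(cpm, mask, ddof=params.cv_ddof)
        frames.append(compute_measures(frame, measures, params, cpm))
    if not frames:
        return VariabilityTable()
    return VariabilityTable(pd.concat(frames, ignore_index=True))


def median_across_tissues(table: VariabilityTable, measure: str) -> pd.Series:
    """Per-gene median score over the tissues in which the gene is scored."""
    sub = table.table[table.table["measure"] == measure]
    if sub.empty:
        raise ValidationError(f"table holds no {measure} entries")
    return sub.groupby("gene_id")["score"].median()
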