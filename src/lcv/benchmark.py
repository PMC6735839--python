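"""Evaluation harness for variability measures.

Four diagnostics, each answering a question a measure must pass before
it can be trusted on heterogeneous expression data:

* expression bias — does the score correlate with expression level?
* robustness — how much do scores move when half the donors are dropped?
* window sensitivity — how stable is LCV under the window-size choice?
* measure correlations — how does LCV relate to the other measures?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datamodel import (
    CountMatrix,
    SampleMeta,
    ValidationError,
    VariabilityParams,
    VariabilityTable,
)
from .preprocess import tmm_factors, to_cpm
from .variability import SortedGeneFrame, compute_all, lcv

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression bias


def expression_bias(table: VariabilityTable, measure: str) -> pd.Series:
    """Spearman r between score and median expression, per tissue.

    The returned series carries one entry per usable tissue plus a
    ``"median"`` entry, the median r over tissues. An unbiased measure
    has r near 0; SD-like measures approach +1 and CV-like measures are
    pushed negative by the mean-dispersion trend of RNA-seq counts.
    """
    out = {}
    for tissue in table.tissues():
        sub = table.table[
            (table.table["measure"] == measure) & (table.table["tissue"] == tissue)
        ]
        if len(sub) < 3:
            logger.warning("tissue %s: <3 genes scored by %s; skipped", tissue, measure)
            continue
        r, _ = spearmanr(sub["score"], sub["median_expression"])
        out[tissue] = float(r)
    if not out:
        raise ValidationError(f"no tissue has >=3 genes scored by {measure}")
    result = pd.Series(out)
    result["median"] = result.median()
    return result


# ---------------------------------------------------------------------------
# robustness to data incompleteness


@dataclass
class SubsetPlan:
    """Reproducible per-(tissue, subset) donor draws.

    Each subset holds ceil(fraction * n) samples drawn without
    replacement; the draws come from child seeds (master seed, tissue
    index, subset index) so adding tissues leaves existing subsets
    untouched.
    """

    n_subsets: int
    fraction: float
    seed: int
    subsets: dict[str, list[list[str]]]  # tissue -> [sample id list per subset]


def make_subset_plan(
    meta: SampleMeta,
    n_subsets: int = 5,
    fraction: float = 0.5,
    seed: int = 0,
    tissues: list[str] | None = None,
) -> SubsetPlan:
    if tissues is None:
        tissues = meta.tissues()
    subsets: dict[str, list[list[str]]] = {}
    for t_idx, tissue in enumerate(sorted(tissues)):
        samples = np.array(meta.samples_of(tissue), dtype=object)
        size = int(np.ceil(fraction * len(samples)))
        if size < 2:
            raise ValidationError(
                f"tissue {tissue}: subsets of size {size} cannot support variability"
            )
        per_tissue = []
        for s_idx in range(n_subsets):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed) % (2**31), t_idx, s_idx])
            )
            chosen = rng.choice(samples, size=size, replace=False)
            per_tissue.append(sorted(chosen))
        subsets[tissue] = per_tissue
    return SubsetPlan(n_subsets=n_subsets, fraction=fraction, seed=seed, subsets=subsets)


@dataclass
class RobustnessReport:
    measure: str
    per_gene_cv: pd.DataFrame  # columns: gene_id, tissue, cv_of_scores
    pooled_median: float
    n_dropped_incomplete: int  # genes not scored in every subset
    n_dropped_zero_mean: int  # |mean score| below tolerance


def robustness(
    counts_by_tissue: dict[str, CountMatrix],
    measure: str,
    params: VariabilityParams,
    plan: SubsetPlan,
    zero_mean_tol: float = 1e-12,
) -> RobustnessReport:
    """Variation of a measure's scores across the plan's donor subsets.

    Recomputes the full pipeline (TMM, cpm, mask, frame, measure) on
    each subset; for every (gene, tissue) scored in *all* subsets the
    variation is CV-of-scores = sd / |mean|. Low pooled medians mean the
    measure is robust to data incompleteness. Genes whose mean score is
    ~0 (possible for signed measures like DM) are excluded and counted.
    """
    rows = []
    dropped_incomplete = 0
    dropped_zero = 0
    for tissue in sorted(counts_by_tissue):
        if tissue not in plan.subsets:
            raise ValidationError(f"plan does not cover tissue {tissue}")
        counts = counts_by_tissue[tissue]
        score_frames = []
        for subset_samples in plan.subsets[tissue]:
            sub = counts.subset_samples(subset_samples)
            factors = tmm_factors(sub)
            cpm = to_cpm(sub, factors, tissue=tissue)
            table = compute_all({tissue: cpm}, params, measures=(measure,))
            score_frames.append(table.scores(measure, tissue))
        scores = pd.concat(score_frames, axis=1, join="outer")
        complete = scores.dropna()
        dropped_incomplete += len(scores) - len(complete)
        mean = complete.mean(axis=1)
        sd = complete.std(axis=1, ddof=1)
        ok = mean.abs() > zero_mean_tol
        dropped_zero += int((~ok).sum())
        cv_scores = (sd[ok] / mean[ok].abs()).rename("cv_of_scores")
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": cv_scores.index,
                    "tissue": tissue,
                    "cv_of_scores": cv_scores.to_numpy(),
                }
            )
        )
    per_gene = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["gene_id", "tissue", "cv_of_scores"]
    )
    pooled = float(per_gene["cv_of_scores"].median()) if len(per_gene) else float("nan")
    return RobustnessReport(
        measure=measure,
        per_gene_cv=per_gene,
        pooled_median=pooled,
        n_dropped_incomplete=dropped_incomplete,
        n_dropped_zero_mean=dropped_zero,
    )


# ---------------------------------------------------------------------------
# window sensitivity


def window_sensitivity(
    frame: SortedGeneFrame,
    windows: tuple[int, ...] = (10, 100, 500, 1000, 10000),
) -> pd.DataFrame:
    """Pairwise Spearman correlations between LCV vectors per window size."""
    vectors = {w: lcv(frame, w).to_numpy() for w in windows}
    out = pd.DataFrame(1.0, index=list(windows), columns=list(windows))
    for i, wa in enumerate(windows):
        for wb in windows[i + 1:]:
            r, _ = spearmanr(vectors[wa], vectors[wb])
            out.loc[wa, wb] = out.loc[wb, wa] = float(r)
    return out


# ---------------------------------------------------------------------------
# cross-measure correlations


def measure_correlations(
    table: VariabilityTable, reference: str = "LCV"
) -> pd.DataFrame:
    """Spearman r between the reference measure and every other, per tissue.

    Returns a tissue x measure frame with a final ``median`` row; pairs
    with fewer than 3 commonly scored genes are skipped (NaN).
    """
    others = [m for m in table.measures() if m != reference]
    if not others or reference not in table.measures():
        raise ValidationError("need the reference measure plus at least one other")
    tissues = table.tissues()
    out = pd.DataFrame(np.nan, index=tissues, columns=others)
    for tissue in tissues:
        ref_scores = table.scores(reference, tissue)
        for other in others:
            other_scores = table.scores(other, tissue)
            common = ref_scores.index.intersection(other_scores.index)
            if len(common) < 3:
                logger.warning(
                    "tissue %s: <3 genes shared by %s and %s; skipped",
                    tissue, reference, other,
                )
                continue
            r, _ = spearmanr(ref_scores[common], other_scores[common])
            out.loc[tissue, other] = float(r)
    out.loc["median"] = out.median()
    return out
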