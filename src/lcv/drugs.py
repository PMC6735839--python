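"""Drug-target variability statistics.

Each drug is summarized by its *most variable target* — the maximum of
its targets' median-across-tissue LCV — and that summary is related to
relative efficacy (RE) scores mined from outcome reports, to
approved-vs-withdrawn status, to anatomical (ATC level-1) drug groups,
and to donor sex. Gene-level analyses relate variability to essentiality
and cluster the gene x tissue LCV matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.spatial.distance import squareform

from .datamodel import (
    CountMatrix,
    DrugRecord,
    EssentialityTable,
    GeneAnnotation,
    REReportTable,
    SampleMeta,
    ValidationError,
    VariabilityParams,
    VariabilityTable,
)
from .preprocess import select_tissues, tmm_factors, to_cpm
from .variability import compute_all, median_across_tissues

logger = logging.getLogger(__name__)


def relative_efficacy(n_ineffective: int, n_most_common: int) -> float:
    """RE = 1 - n_ineffective / n_most_common_complaint, in [0, 1].

    Close to 1 when a drug has almost no ineffective reports; close to 0
    when "ineffective" dominates the complaints. The >= 10-report
    eligibility floor is the caller's responsibility.
    """
    if n_most_common <= 0:
        raise ValidationError("n_most_common_complaint must be positive")
    if n_ineffective < 0 or n_ineffective > n_most_common:
        raise ValidationError("need 0 <= n_ineffective <= n_most_common_complaint")
    return 1.0 - n_ineffective / n_most_common


@dataclass
class DrugScore:
    drug_id: str
    max_target_lcv: float
    max_target_gene: str
    status: str
    atc_level1: frozenset[str] = field(default_factory=frozenset)
    median_re: float | None = None


def drug_scores(
    drugs: list[DrugRecord],
    gene_lcv: pd.Series,
    reports: REReportTable | None = None,
) -> tuple[list[DrugScore], int]:
    """Attach each drug's most variable scored target (and median RE).

    Drugs none of whose targets carry a score are excluded; the second
    return value counts them. Ties on the maximum go to the
    lexicographically first gene.
    """
    if gene_lcv.empty:
        raise ValidationError("gene_lcv is empty")
    median_re = reports.median_re_per_drug() if reports is not None else pd.Series(dtype=float)
    out = []
    n_unscored = 0
    for drug in drugs:
        scored = sorted(t for t in drug.target_gene_ids if t in gene_lcv.index)
        if not scored:
            n_unscored += 1
            continue
        values = gene_lcv[scored].to_numpy(dtype=float)
        best = int(np.argmax(values))  # argmax takes the first max: lexicographic tie-break
        out.append(
            DrugScore(
                drug_id=drug.drug_id,
                max_target_lcv=float(values[best]),
                max_target_gene=scored[best],
                status=drug.status,
                atc_level1=drug.atc_level1,
                median_re=float(median_re[drug.drug_id])
                if drug.drug_id in median_re.index
                else None,
            )
        )
    return out, n_unscored


def re_lcv_correlation(scores: list[DrugScore]) -> tuple[float, float, int]:
    """Spearman r (and two-sided p) between median RE and max-target LCV."""
    pairs = [(s.median_re, s.max_target_lcv) for s in scores if s.median_re is not None]
    if len(pairs) < 3:
        raise ValidationError("need >= 3 drugs with both RE and LCV")
    re, lcv_values = zip(*pairs)
    if len(set(re)) < 2 or len(set(lcv_values)) < 2:
        raise ValidationError("correlation undefined: a variable is constant")
    r, p = stats.spearmanr(re, lcv_values)
    return float(r), float(p), len(pairs)


@dataclass
class ContrastResult:
    n_approved: int
    n_withdrawn: int
    median_approved: float
    median_withdrawn: float
    mannwhitney_u: float
    mannwhitney_p: float
    ks_p: float
    lcv_cut: float
    frac_above_approved: float
    frac_above_withdrawn: float
    hypergeom_p: float


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # exact when both groups are small and tie-free, else normal
    # approximation with tie correction
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    small = max(len(x), len(y)) <= 25
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def status_contrast(scores: list[DrugScore], lcv_cut: float = 90.0) -> ContrastResult:
    """Approved-vs-withdrawn contrast of max-target LCV.

    Reports two-sided Mann-Whitney and Kolmogorov-Smirnov tests, group
    medians, the fraction of each group strictly above ``lcv_cut``, and
    an upper-tail hypergeometric p for over-representation of withdrawn
    drugs among the high-variability (> cut) drugs in the pooled set.
    """
    approved = np.array([s.max_target_lcv for s in scores if s.status == "approved"])
    withdrawn = np.array([s.max_target_lcv for s in scores if s.status == "withdrawn"])
    if len(approved) == 0 or len(withdrawn) == 0:
        raise ValidationError("both status groups must be non-empty")
    u, mw_p = _mannwhitney(withdrawn, approved)
    ks_p = float(stats.ks_2samp(withdrawn, approved, method="auto").pvalue)
    n_total = len(approved) + len(withdrawn)
    n_high = int((approved > lcv_cut).sum() + (withdrawn > lcv_cut).sum())
    k_withdrawn_high = int((withdrawn > lcv_cut).sum())
    # P(X >= k) for X ~ Hypergeom(N=n_total, K=n_high, n=len(withdrawn))
    hg_p = float(stats.hypergeom.sf(k_withdrawn_high - 1, n_total, n_high, len(withdrawn)))
    return ContrastResult(
        n_approved=len(approved),
        n_withdrawn=len(withdrawn),
        median_approved=float(np.median(approved)),
        median_withdrawn=float(np.median(withdrawn)),
        mannwhitney_u=u,
        mannwhitney_p=mw_p,
        ks_p=ks_p,
        lcv_cut=lcv_cut,
        frac_above_approved=float((approved > lcv_cut).mean()),
        frac_above_withdrawn=float((withdrawn > lcv_cut).mean()),
        hypergeom_p=hg_p,
    )


def atc_stratified(
    scores: list[DrugScore], min_n: int = 10
) -> tuple[dict[str, dict], list[str]]:
    """Per-ATC-level-1 RE/LCV correlation and status contrast.

    A drug carrying several codes contributes to each of its groups. A
    group enters the correlation analysis only with >= ``min_n`` complete
    (RE + LCV) observations; the contrast additionally needs both status
    groups non-empty. Undersized groups are returned as skipped.
    """
    by_code: dict[str, list[DrugScore]] = {}
    for score in scores:
        for code in score.atc_level1:
            by_code.setdefault(code, []).append(score)
    results: dict[str, dict] = {}
    skipped: list[str] = []
    for code in sorted(by_code):
        group = by_code[code]
        complete = [s for s in group if s.median_re is not None]
        if len(complete) < min_n:
            skipped.append(code)
            continue
        entry: dict = {"n": len(group), "n_complete": len(complete)}
        try:
            r, p, n = re_lcv_correlation(complete)
            entry["re_lcv_r"], entry["re_lcv_p"] = r, p
        except ValidationError as exc:
            entry["re_lcv_error"] = str(exc)
        try:
            entry["contrast"] = status_contrast(group)
        except ValidationError as exc:
            entry["contrast_error"] = str(exc)
        results[code] = entry
    return results, skipped


def essentiality_association(
    gene_lcv: pd.Series,
    essentiality: EssentialityTable,
    top_fraction: float = 0.1,
) -> dict:
    """Relate variability to essentiality (negated growth-impact scores).

    Returns the Spearman r/p between per-gene negated median essentiality
    and median LCV over the shared genes, plus median LCV inside and
    outside the essential (top ``top_fraction``) group.
    """
    per_gene = essentiality.per_gene(top_fraction=top_fraction)
    common = per_gene.index.intersection(gene_lcv.index)
    if len(common) < 3:
        raise ValidationError("fewer than 3 genes shared with the essentiality screen")
    ess = per_gene.loc[common]
    lcv_values = gene_lcv[common]
    r, p = stats.spearmanr(ess["neg_median_score"], lcv_values)
    essential_mask = ess["is_essential"]
    return {
        "n": int(len(common)),
        "spearman_r": float(r),
        "spearman_p": float(p),
        "n_essential": int(essential_mask.sum()),
        "median_lcv_essential": float(lcv_values[essential_mask].median())
        if essential_mask.any()
        else float("nan"),
        "median_lcv_other": float(lcv_values[~essential_mask].median())
        if (~essential_mask).any()
        else float("nan"),
    }


@dataclass
class SexComparison:
    per_drug: pd.DataFrame  # drug_id, lcv_female, lcv_male, delta, flagged
    pearson_r: float
    flagged: list[str]  # |delta| > threshold
    tissues_used: list[str]
    delta_threshold: float


def sex_stratified(
    counts: CountMatrix,
    meta: SampleMeta,
    annotation: GeneAnnotation,
    drugs: list[DrugRecord],
    params: VariabilityParams,
    min_per_sex: int = 5,
    delta_threshold: float = 10.0,
    min_samples_per_tissue: int = 10,
) -> SexComparison:
    """Per-sex variability pipeline and per-drug LCV differences.

    Keeps tissues with >= ``min_per_sex`` samples of *both* sexes, drops
    X/Y genes, runs the full TMM/cpm/LCV pipeline separately per sex, and
    compares each drug's max-target median LCV between sexes. ``delta``
    is female minus male; drugs with |delta| > ``delta_threshold`` are
    flagged.
    """
    meta.check_covers(counts)
    sex_genes = annotation.sex_chromosome_genes()
    autosomal = [g for g in counts.gene_ids if g not in sex_genes]
    counts = counts.subset_genes(autosomal)

    eligible = []
    for tissue, samples in select_tissues(meta, min_samples=min_samples_per_tissue):
        sexes = meta.table.loc[samples, "sex"]
        if (sexes == "female").sum() >= min_per_sex and (sexes == "male").sum() >= min_per_sex:
            eligible.append(tissue)
    if not eligible:
        raise ValidationError(
            f"no tissue has >= {min_per_sex} samples of each sex"
        )

    per_sex_lcv: dict[str, pd.Series] = {}
    for sex in ("female", "male"):
        cpm_by_tissue = {}
        for tissue in eligible:
            samples = [
                s for s in meta.samples_of(tissue)
                if meta.table.loc[s, "sex"] == sex and s in counts.sample_ids
            ]
            sub = counts.subset_samples(samples)
            cpm_by_tissue[tissue] = to_cpm(sub, tmm_factors(sub), tissue=tissue)
        table = compute_all(cpm_by_tissue, params, measures=("LCV",))
        if not len(table):
            raise ValidationError(f"no genes scored for sex {sex}")
        per_sex_lcv[sex] = median_across_tissues(table, "LCV")

    scores_f, _ = drug_scores(drugs, per_sex_lcv["female"])
    scores_m, _ = drug_scores(drugs, per_sex_lcv["male"])
    female = {s.drug_id: s.max_target_lcv for s in scores_f}
    male = {s.drug_id: s.max_target_lcv for s in scores_m}
    common = sorted(set(female) & set(male))
    if len(common) < 2:
        raise ValidationError("fewer than 2 drugs scored in both sexes")
    per_drug = pd.DataFrame(
        {
            "drug_id": common,
            "lcv_female": [female[d] for d in common],
            "lcv_male": [male[d] for d in common],
        }
    )
    per_drug["delta"] = per_drug["lcv_female"] - per_drug["lcv_male"]
    per_drug["flagged"] = per_drug["delta"].abs() > delta_threshold
    if per_drug["lcv_female"].nunique() < 2 or per_drug["lcv_male"].nunique() < 2:
        pearson = float("nan")
    else:
        pearson = float(stats.pearsonr(per_drug["lcv_female"], per_drug["lcv_male"])[0])
    return SexComparison(
        per_drug=per_drug,
        pearson_r=pearson,
        flagged=list(per_drug.loc[per_drug["flagged"], "drug_id"]),
        tissues_used=eligible,
        delta_threshold=delta_threshold,
    )


# ---------------------------------------------------------------------------
# clustering of the gene x tissue LCV matrix


@dataclass
class ClusterResult:
    gene_linkage: np.ndarray
    tissue_linkage: np.ndarray
    gene_ids: list[str]
    tissues: list[str]
    gene_clusters: pd.Series  # gene_id -> cluster label 1..k


def cluster_lcv_matrix(table: VariabilityTable, k: int = 3) -> ClusterResult:
    """Cluster globally expressed genes and tissues by their LCV profiles.

    Genes: Ward linkage on raw Euclidean distances between gene LCV
    vectors (the ward.D2 convention). Tissues: Ward linkage on
    1 - Spearman r between tissue LCV vectors. Only genes scored in
    every tissue enter. Returns the two linkage trees and a k-cluster
    cut of the gene tree.
    """
    wide = table.pivot("LCV").dropna()
    if wide.shape[1] < 2:
        raise ValidationError("need at least 2 tissues to cluster")
    if wide.shape[0] < 3:
        raise ValidationError("need at least 3 globally scored genes")
    gene_linkage = sch.linkage(wide.to_numpy(), method="ward")
    if wide.shape[1] == 2:
        r = float(stats.spearmanr(wide.iloc[:, 0], wide.iloc[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(stats.spearmanr(wide.to_numpy()).statistic)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    tissue_linkage = sch.linkage(squareform(dist, checks=False), method="ward")
    labels = sch.fcluster(gene_linkage, t=k, criterion="maxclust")
    return ClusterResult(
        gene_linkage=gene_linkage,
        tissue_linkage=tissue_linkage,
        gene_ids=list(wide.index),
        tissues=list(wide.columns),
        gene_clusters=pd.Series(labels, index=wide.index),
    )


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage tree as a newick string with branch lengths."""
    tree = sch.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
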