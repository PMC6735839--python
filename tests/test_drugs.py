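"""Drug-level statistics against exact combinatorial oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcv.datamodel import (
    DrugRecord,
    EssentialityTable,
    REReportTable,
    ValidationError,
    VariabilityParams,
)
from lcv.drugs import (
    DrugScore,
    cluster_lcv_matrix,
    drug_scores,
    essentiality_association,
    linkage_to_newick,
    re_lcv_correlation,
    relative_efficacy,
    sex_stratified,
    status_contrast,
    atc_stratified,
)


def make_score(drug_id, lcv_value, status="approved", re=None, atc=()):
    return DrugScore(
        drug_id=drug_id,
        max_target_lcv=lcv_value,
        max_target_gene="G",
        status=status,
        median_re=re,
        atc_level1=frozenset(atc),
    )


class TestRelativeEfficacy:
    @pytest.mark.parametrize(
        "ineffective,most_common,expected",
        [(0, 10, 1.0), (10, 10, 0.0), (3, 12, 0.75)],
    )
    def test_values(self, ineffective, most_common, expected):
        assert relative_efficacy(ineffective, most_common) == pytest.approx(expected)

    @pytest.mark.parametrize("args", [(1, 0), (5, 4), (-1, 10)])
    def test_invalid_counts_rejected(self, args):
        with pytest.raises(ValidationError):
            relative_efficacy(*args)

    @given(st.integers(min_value=1, max_value=10_000), st.data())
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_affine(self, most, data):
        ineff = data.draw(st.integers(min_value=0, max_value=most))
        re = relative_efficacy(ineff, most)
        assert 0.0 <= re <= 1.0
        if ineff + 1 <= most:  # affine: each extra ineffective report costs 1/most
            step = re - relative_efficacy(ineff + 1, most)
            assert step == pytest.approx(1.0 / most)


class TestDrugScores:
    GENE_LCV = pd.Series({"A": 50.0, "B": 79.5, "KCNH2": 79.5, "Z": 10.0})

    def drug(self, drug_id, targets, status="approved"):
        return DrugRecord(
            drug_id=drug_id, name=drug_id, status=status,
            target_gene_ids=frozenset(targets),
        )

    def test_single_target(self):
        scores, n = drug_scores([self.drug("D1", {"A"})], self.GENE_LCV)
        assert n == 0
        assert scores[0].max_target_gene == "A"
        assert scores[0].max_target_lcv == 50.0

    def test_max_tie_goes_to_lexicographically_first(self):
        scores, _ = drug_scores([self.drug("D1", {"KCNH2", "B", "Z"})], self.GENE_LCV)
        assert scores[0].max_target_gene == "B"  # B and KCNH2 tie at 79.5
        assert scores[0].max_target_lcv == 79.5

    def test_unscored_targets_ignored_and_counted(self):
        drugs = [self.drug("D1", {"A", "nope"}), self.drug("D2", {"missing"})]
        scores, n_unscored = drug_scores(drugs, self.GENE_LCV)
        assert [s.drug_id for s in scores] == ["D1"]
        assert n_unscored == 1

    def test_median_re_attached(self):
        reports = REReportTable(
            pd.DataFrame(
                {
                    "drug_id": ["D1", "D1"],
                    "disease": ["x", "y"],
                    "n_ineffective": [8, 2],
                    "n_most_common_complaint": [10, 10],
                }
            )
        )
        scores, _ = drug_scores([self.drug("D1", {"A"})], self.GENE_LCV, reports)
        assert scores[0].median_re == pytest.approx(0.5)  # median of {0.2, 0.8}

    def test_invariant_to_duplicate_targets(self):
        a = drug_scores([self.drug("D1", {"A", "B"})], self.GENE_LCV)[0][0]
        b = drug_scores([self.drug("D1", {"B", "A", "B"})], self.GENE_LCV)[0][0]
        assert (a.max_target_gene, a.max_target_lcv) == (b.max_target_gene, b.max_target_lcv)


class TestReLcvCorrelation:
    def test_planted_monotone_decreasing(self):
        scores = [make_score(f"D{i}", float(i), re=1.0 - i / 10.0) for i in range(8)]
        r, p, n = re_lcv_correlation(scores)
        assert r == pytest.approx(-1.0)
        assert n == 8

    def test_constant_re_is_an_error_not_zero(self):
        scores = [make_score(f"D{i}", float(i), re=0.5) for i in range(5)]
        with pytest.raises(ValidationError, match="constant"):
            re_lcv_correlation(scores)

    def test_too_few_observations_rejected(self):
        scores = [make_score("D1", 1.0, re=0.5), make_score("D2", 2.0, re=0.6)]
        with pytest.raises(ValidationError):
            re_lcv_correlation(scores)


def mannwhitney_oracle(x, y):
    """Two-sided exact MW p by enumerating all label assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    us = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(
            sum(1 for a in xs for b in ys if a > b)
            + 0.5 * sum(1 for a in xs for b in ys if a == b)
        )
    us = np.array(us)
    p_ge = np.mean(us >= u_obs)
    p_le = np.mean(us <= u_obs)
    return min(1.0, 2.0 * min(p_ge, p_le))


def hypergeom_oracle(k, n_total, n_high, n_draw):
    """Upper-tail P(X >= k) by direct combinatorial summation."""
    total = 0.0
    for j in range(k, min(n_high, n_draw) + 1):
        total += (
            math.comb(n_high, j)
            * math.comb(n_total - n_high, n_draw - j)
            / math.comb(n_total, n_draw)
        )
    return total


class TestStatusContrast:
    def test_identical_groups_near_null(self):
        values = [10.0, 30.0, 50.0, 70.0, 95.0]
        scores = [make_score(f"A{i}", v, "approved") for i, v in enumerate(values)]
        scores += [make_score(f"W{i}", v, "withdrawn") for i, v in enumerate(values)]
        result = status_contrast(scores)
        assert result.mannwhitney_p >= 0.9
        assert result.frac_above_approved == result.frac_above_withdrawn

    def test_hypergeometric_exact_value(self):
        # 10 drugs, 5 above the cut, all 5 withdrawn above: p = 1/C(10,5)
        scores = [make_score(f"W{i}", 95.0, "withdrawn") for i in range(5)]
        scores += [make_score(f"A{i}", 50.0, "approved") for i in range(5)]
        result = status_contrast(scores, lcv_cut=90.0)
        assert result.hypergeom_p == pytest.approx(1.0 / 252.0)

    def test_cut_is_strict(self):
        scores = [
            make_score("W1", 90.0, "withdrawn"),  # exactly at the cut: not above
            make_score("W2", 90.1, "withdrawn"),
            make_score("A1", 50.0, "approved"),
        ]
        result = status_contrast(scores, lcv_cut=90.0)
        assert result.frac_above_withdrawn == pytest.approx(0.5)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_small_sample_p_values_match_enumeration(self, data):
        rng_seed = data.draw(st.integers(min_value=0, max_value=10_000))
        rng = np.random.default_rng(rng_seed)
        n_a = data.draw(st.integers(min_value=2, max_value=6))
        n_w = data.draw(st.integers(min_value=2, max_value=6))
        values = rng.uniform(0, 100, n_a + n_w)  # continuous: no ties
        scores = [make_score(f"A{i}", v, "approved") for i, v in enumerate(values[:n_a])]
        scores += [
            make_score(f"W{i}", v, "withdrawn")
            for i, v in enumerate(values[n_a:])
        ]
        result = status_contrast(scores)
        expected_mw = mannwhitney_oracle(values[n_a:], values[:n_a])
        assert result.mannwhitney_p == pytest.approx(expected_mw, rel=1e-9)
        n_high = int((values > 90).sum())
        k = int((values[n_a:] > 90).sum())
        assert result.hypergeom_p == pytest.approx(
            hypergeom_oracle(k, n_a + n_w, n_high, n_w), rel=1e-9
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            status_contrast([make_score("A1", 10.0, "approved")])


class TestAtcStratified:
    def make_scores(self, n, atc, offset=0):
        return [
            make_score(f"D{offset + i}", float(10 + i), re=1.0 - i / (2 * n), atc=atc)
            for i in range(n)
        ]

    def test_small_group_skipped(self):
        results, skipped = atc_stratified(self.make_scores(9, ("A",)), min_n=10)
        assert skipped == ["A"]
        assert results == {}

    def test_multi_code_drug_counts_in_each_group(self):
        scores = self.make_scores(12, ("A", "C"))
        results, skipped = atc_stratified(scores, min_n=10)
        assert set(results) == {"A", "C"}
        assert results["A"]["n_complete"] == 12
        assert results["C"]["n_complete"] == 12

    def test_single_group_matches_direct_correlation(self):
        scores = self.make_scores(15, ("N",))
        results, _ = atc_stratified(scores, min_n=10)
        r, p, n = re_lcv_correlation(scores)
        assert results["N"]["re_lcv_r"] == pytest.approx(r)
        assert results["N"]["re_lcv_p"] == pytest.approx(p)


class TestEssentiality:
    def test_negation_and_top_decile(self):
        table = EssentialityTable(
            pd.DataFrame(
                {
                    "gene_id": [f"G{i:03d}" for i in range(100)],
                    "cell_line": ["c"] * 100,
                    "score": -np.arange(100.0),
                }
            )
        )
        gene_lcv = pd.Series(
            np.arange(100.0), index=[f"G{i:03d}" for i in range(100)]
        )
        result = essentiality_association(gene_lcv, table)
        assert result["n_essential"] == 10
        # most essential genes (G090..G099) have the highest LCV here
        assert result["median_lcv_essential"] > result["median_lcv_other"]

    def test_planted_perfect_anti_relation(self):
        genes = [f"G{i:02d}" for i in range(50)]
        table = EssentialityTable(
            pd.DataFrame(
                {"gene_id": genes, "cell_line": "c", "score": -np.arange(50.0)}
            )
        )
        gene_lcv = pd.Series(100.0 - np.arange(50.0) * 2, index=genes)
        result = essentiality_association(gene_lcv, table)
        assert result["spearman_r"] == pytest.approx(-1.0)

    def test_no_overlap_rejected(self):
        table = EssentialityTable(
            pd.DataFrame({"gene_id": ["A", "B", "C"], "cell_line": "c",
                          "score": [-1.0, -2.0, -3.0]})
        )
        with pytest.raises(ValidationError):
            essentiality_association(pd.Series({"X": 1.0}), table)


class TestSexStratified:
    def _base(self, small_dataset):
        from lcv.synthetic import simulate_drugs

        config, counts, meta, annotation, truth = small_dataset
        drugs = simulate_drugs(config, truth)
        return counts, meta, annotation, drugs

    def test_identical_sexes_give_zero_deltas(self, small_dataset):
        counts, meta, annotation, drugs = self._base(small_dataset)
        # mirror every sample into one male and one female copy
        doubled = pd.concat(
            [
                counts.counts.rename(columns=lambda s: s + "_f"),
                counts.counts.rename(columns=lambda s: s + "_m"),
            ],
            axis=1,
        )
        meta_rows = pd.concat(
            [
                meta.table.assign(sex="female").rename(index=lambda s: s + "_f"),
                meta.table.assign(sex="male").rename(index=lambda s: s + "_m"),
            ]
        )
        from lcv.datamodel import CountMatrix, SampleMeta

        comparison = sex_stratified(
            CountMatrix(doubled),
            SampleMeta(meta_rows),
            annotation,
            drugs,
            VariabilityParams(window_m=50),
            min_per_sex=5,
        )
        assert np.allclose(comparison.per_drug["delta"], 0.0)
        assert comparison.flagged == []

    def test_sex_chromosome_genes_excluded(self, small_dataset):
        counts, meta, annotation, drugs = self._base(small_dataset)
        comparison = sex_stratified(
            counts, meta, annotation, drugs, VariabilityParams(window_m=50),
            min_per_sex=3,
        )
        sex_genes = annotation.sex_chromosome_genes()
        scored_best = set(comparison.per_drug["drug_id"])
        by_id = {d.drug_id: d for d in drugs}
        only_sex_target_drugs = {
            d.drug_id for d in drugs if d.target_gene_ids <= sex_genes
        }
        assert scored_best.isdisjoint(only_sex_target_drugs)

    def test_flagging_threshold(self):
        # direct check of the |delta| > 10 rule on a hand-built comparison
        per_drug = pd.DataFrame(
            {
                "drug_id": ["D1", "D2"],
                "lcv_female": [90.0, 70.0],
                "lcv_male": [66.2, 68.0],
            }
        )
        per_drug["delta"] = per_drug["lcv_female"] - per_drug["lcv_male"]
        flagged = per_drug.loc[per_drug["delta"].abs() > 10.0, "drug_id"]
        assert list(flagged) == ["D1"]
        assert per_drug.loc[0, "delta"] == pytest.approx(23.8)


class TestClustering:
    def lcv_table(self, matrix, genes, tissues):
        from lcv.datamodel import VariabilityTable

        rows = []
        for i, g in enumerate(genes):
            for j, t in enumerate(tissues):
                rows.append(
                    {
                        "gene_id": g,
                        "tissue": t,
                        "measure": "LCV",
                        "score": matrix[i][j],
                        "median_expression": 1.0,
                    }
                )
        return VariabilityTable(pd.DataFrame(rows))

    def test_duplicate_genes_and_tissues_merge_at_zero(self):
        rng = np.random.default_rng(12)
        base = rng.uniform(0, 100, size=(6, 3))
        matrix = np.column_stack([base, base[:, 2]])  # duplicated tissue column
        matrix[1] = matrix[0]  # duplicated gene row
        table = self.lcv_table(matrix, [f"G{i}" for i in range(6)],
                               ["t1", "t2", "t3", "t4"])
        result = cluster_lcv_matrix(table)
        assert result.gene_linkage[0, 2] == pytest.approx(0.0)
        assert result.tissue_linkage[0, 2] == pytest.approx(0.0)

    def test_three_planted_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(42)
        centers = [10.0, 50.0, 90.0]
        rows, labels = [], []
        for label, center in enumerate(centers):
            for _ in range(30):
                rows.append(np.clip(rng.normal(center, 5.0, 5), 0, 100))
                labels.append(label)
        table = self.lcv_table(rows, [f"G{i:03d}" for i in range(90)],
                               [f"t{j}" for j in range(5)])
        result = cluster_lcv_matrix(table, k=3)
        ari = adjusted_rand_score(labels, result.gene_clusters.to_numpy())
        assert ari == 1.0

    def test_newick_renders_all_labels(self):
        rng = np.random.default_rng(1)
        table = self.lcv_table(rng.uniform(0, 100, (5, 3)),
                               list("abcde"), ["t1", "t2", "t3"])
        result = cluster_lcv_matrix(table)
        newick = linkage_to_newick(result.gene_linkage, result.gene_ids)
        assert newick.endswith(";")
        for label in "abcde":
            assert label in newick
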