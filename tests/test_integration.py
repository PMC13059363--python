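import math

import numpy as np
import pandas as pd
import pytest

from methexp import integration as im


GENES = pd.DataFrame(
    [("gp", "A01", 10_000, 12_000, "+"), ("gm", "A01", 30_000, 32_000, "-")],
    columns=["gene_id", "chrom", "start", "end", "strand"],
)


def _conserved(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "group", "direction",
                 "n_support", "mean_delta", "genotype_ids"],
    )


class TestAssociateDmrsToGenes:
    def test_dmr_inside_body_links_as_gene_body(self):
        c = _conserved([("A01", 10_500, 10_700, "CHH", "s", "hyper", 3, 0.3, "x")])
        links = im.associate_dmrs_to_genes(c, GENES)
        assert len(links) == 1
        assert links.iloc[0].placement == "gene_body"
        assert links.iloc[0].gene_id == "gp"

    def test_tss_spanning_dmr_takes_body_precedence(self):
        c = _conserved([("A01", 9_900, 10_100, "CHH", "s", "hyper", 3, 0.3, "x")])
        links = im.associate_dmrs_to_genes(c, GENES)
        assert links.iloc[0].placement == "gene_body"

    def test_dmr_beyond_two_kb_not_linked(self):
        c = _conserved([("A01", 7_000, 7_999, "CHH", "s", "hyper", 3, 0.3, "x")])
        assert len(im.associate_dmrs_to_genes(c, GENES)) == 0

    def test_minus_strand_flanks_are_strand_aware(self):
        up = _conserved([("A01", 32_500, 32_700, "CHH", "s", "hyper", 3, 0.3, "x")])
        assert im.associate_dmrs_to_genes(up, GENES).iloc[0].placement == "upstream2k"
        down = _conserved([("A01", 28_500, 28_700, "CHH", "s", "hyper", 3, 0.3, "x")])
        assert im.associate_dmrs_to_genes(down, GENES).iloc[0].placement == "downstream2k"

    def test_one_dmr_may_link_multiple_genes(self):
        genes = pd.DataFrame(
            [("a", "A01", 1000, 2000, "+"), ("b", "A01", 2500, 3500, "+")],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        )
        c = _conserved([("A01", 1900, 2600, "CHH", "s", "hyper", 3, 0.3, "x")])
        links = im.associate_dmrs_to_genes(c, genes)
        assert set(links["gene_id"]) == {"a", "b"}


class TestGeneDeltaMeth:
    def _links(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "dmr_index", "placement", "context", "delta",
                     "start", "end", "chrom"],
        )

    def test_single_dmr_returns_its_delta(self):
        links = self._links([("g", 0, "gene_body", "CHH", 0.30, 0, 100, "A01")])
        assert im.gene_delta_meth(links)["g"] == pytest.approx(0.30)

    def test_two_equal_length_dmrs_average(self):
        links = self._links(
            [("g", 0, "gene_body", "CHH", 0.2, 0, 100, "A01"),
             ("g", 1, "upstream2k", "CHH", 0.4, 200, 300, "A01")]
        )
        assert im.gene_delta_meth(links)["g"] == pytest.approx(0.3)

    def test_length_weighting_within_context(self):
        links = self._links(
            [("g", 0, "gene_body", "CHH", 0.2, 0, 300, "A01"),
             ("g", 1, "upstream2k", "CHH", 0.4, 400, 500, "A01")]
        )
        # lengths 300 and 100 -> (0.2*300 + 0.4*100) / 400 = 0.25
        assert im.gene_delta_meth(links)["g"] == pytest.approx(0.25)

    def test_invariant_to_link_order(self):
        links = self._links(
            [("g", 0, "gene_body", "CG", 0.2, 0, 100, "A01"),
             ("g", 1, "gene_body", "CHH", -0.4, 200, 400, "A01")]
        )
        a = im.gene_delta_meth(links)
        b = im.gene_delta_meth(links.iloc[::-1])
        pd.testing.assert_series_equal(a, b)

    def test_strongest_mode_picks_largest_magnitude(self):
        links = self._links(
            [("g", 0, "gene_body", "CHH", 0.1, 0, 100, "A01"),
             ("g", 1, "upstream2k", "CHH", -0.5, 200, 300, "A01")]
        )
        assert im.gene_delta_meth(links, mode="strongest")["g"] == pytest.approx(-0.5)


class TestNegativeRegulationScreen:
    degs = pd.DataFrame({"gene_id": ["a", "b", "c"], "log2fc": [-1.5, -1.5, 1.5]})

    def test_opposite_signs_above_threshold_kept(self):
        out = im.negative_regulation_screen(pd.Series({"a": 0.10}), self.degs)
        assert list(out["gene_id"]) == ["a"]

    def test_below_methylation_threshold_dropped(self):
        out = im.negative_regulation_screen(pd.Series({"a": 0.04}), self.degs)
        assert len(out) == 0

    def test_threshold_is_strict(self):
        out = im.negative_regulation_screen(pd.Series({"a": 0.05}), self.degs)
        assert len(out) == 0

    def test_same_sign_dropped(self):
        out = im.negative_regulation_screen(pd.Series({"c": 0.10}), self.degs)
        assert len(out) == 0

    def test_output_is_subset_of_both_tables(self):
        rng = np.random.default_rng(0)
        deltas = pd.Series(rng.uniform(-0.3, 0.3, 50), index=[f"g{i}" for i in range(50)])
        degs = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(25, 75)],
             "log2fc": rng.normal(0, 2, 50)}
        )
        out = im.negative_regulation_screen(deltas, degs)
        assert set(out["gene_id"]) <= set(deltas.index) & set(degs["gene_id"])
        for r in out.itertuples(index=False):
            assert abs(r.delta_meth) > 0.05
            assert np.sign(r.delta_meth) != np.sign(r.log2fc)


class TestCorrelationSummary:
    def test_exact_negative_line(self):
        cand = pd.DataFrame({"delta_meth": [0.1, 0.2, 0.3], "log2fc": [-1.0, -2.0, -3.0]})
        out = im.correlation_summary(cand)
        assert out["pearson_r"] == pytest.approx(-1.0)
        assert out["n"] == 3

    def test_degenerate_axis_is_nodata(self):
        cand = pd.DataFrame({"delta_meth": [0.1, 0.1, 0.1], "log2fc": [-1, -2, -3]})
        assert math.isnan(im.correlation_summary(cand)["pearson_r"])

    def test_too_few_pairs_is_nodata_not_error(self):
        cand = pd.DataFrame({"delta_meth": [0.1], "log2fc": [-1.0]})
        out = im.correlation_summary(cand)
        assert math.isnan(out["pearson_r"]) and out["n"] == 1

    def test_25_pair_toy_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.2, 25)
        y = -3 * x + rng.normal(0, 0.5, 25)
        cand = pd.DataFrame({"delta_meth": x, "log2fc": y})
        out = im.correlation_summary(cand)
        expected = np.corrcoef(x, y)[0, 1]
        assert out["pearson_r"] == pytest.approx(expected, abs=1e-12)


class TestPriorityScore:
    def test_worked_example(self):
        # 2.0*1 + 0.30*5 + 1*10 + 1.0*5 + ln(1)*2 = 18.5
        assert im.priority_score(2.0, 0.30, 1, 1.0, 1) == pytest.approx(18.5)

    def test_floor_with_zero_magnitudes(self):
        assert im.priority_score(0.0, 0.0, 1, 0.0, 1) == pytest.approx(10.0)

    def test_doubling_dmr_count_adds_two_ln_two(self):
        a = im.priority_score(1.0, 0.1, 1, 1.0, 4)
        b = im.priority_score(1.0, 0.1, 1, 1.0, 2)
        assert a - b == pytest.approx(2 * math.log(2))

    def test_strictly_increasing_in_each_component(self):
        base = im.priority_score(1.0, 0.2, 1, 0.5, 2)
        assert im.priority_score(1.1, 0.2, 1, 0.5, 2) > base
        assert im.priority_score(1.0, 0.3, 1, 0.5, 2) > base
        assert im.priority_score(1.0, 0.2, 2, 0.5, 2) > base
        assert im.priority_score(1.0, 0.2, 1, 0.6, 2) > base
        assert im.priority_score(1.0, 0.2, 1, 0.5, 3) > base

    def test_invalid_dmr_count_rejected(self):
        with pytest.raises(ValueError):
            im.priority_score(1.0, 0.2, 1, 0.5, 0)

    def test_configurable_log_base(self):
        a = im.priority_score(0, 0, 1, 0, 10, log_base=10)
        assert a == pytest.approx(10 + 2.0)


class TestRankCandidates:
    def test_descending_with_gene_id_tiebreak(self):
        cand = pd.DataFrame(
            {"gene_id": ["b", "a", "c"], "priority_score": [5.0, 5.0, 9.0]}
        )
        out = im.rank_candidates(cand, top_k=3)
        assert list(out["gene_id"]) == ["c", "a", "b"]

    def test_top_k_truncates(self):
        cand = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(30)],
             "priority_score": np.arange(30, dtype=float)}
        )
        out = im.rank_candidates(cand, top_k=15)
        assert len(out) == 15
        assert out.iloc[0].priority_score == 29.0

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(12)
        cand = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(50)],
             "priority_score": rng.choice([1.0, 2.0, 3.0], 50)}
        )
        out = im.rank_candidates(cand, top_k=50)
        expected = sorted(
            cand.itertuples(index=False), key=lambda r: (-r.priority_score, r.gene_id)
        )
        assert list(out["gene_id"]) == [r.gene_id for r in expected]


class TestVennPartition:
    def test_study_scale_partition_sums(self):
        s = [f"s{i}" for i in range(89)] + ["shared0"]
        t = [f"t{i}" for i in range(16)] + ["shared0"]
        out = im.venn_partition(s, t)
        assert out == {
            "sensitive_specific": 89, "tolerant_specific": 16, "common": 1, "total": 106,
        }

    def test_identical_sets(self):
        out = im.venn_partition(["a", "b"], ["a", "b"])
        assert out["sensitive_specific"] == 0 and out["tolerant_specific"] == 0
        assert out["common"] == 2

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            s = set(map(int, rng.choice(100, rng.integers(0, 50), replace=False)))
            t = set(map(int, rng.choice(100, rng.integers(0, 50), replace=False)))
            out = im.venn_partition(s, t)
            assert out["common"] == len(s & t)
            assert out["total"] == len(s | t)


class TestHubGenes:
    cand = pd.DataFrame(
        {"gene_id": ["a", "b"], "delta_meth": [0.1, -0.2], "log2fc": [-2.0, 1.5],
         "n_dmrs": [1, 1]}
    )

    def test_candidate_in_core_pathway_is_hub(self):
        out = im.hub_genes(self.cand, {"P1": ["a", "zzz"]})
        assert list(out["gene_id"]) == ["a"]
        assert out.iloc[0].core_pathways == "P1"

    def test_candidate_in_no_core_pathway_is_not_hub(self):
        out = im.hub_genes(self.cand, {"P1": ["zzz"]})
        assert len(out) == 0

    def test_empty_core_gives_empty_hub_table(self):
        out = im.hub_genes(self.cand, {})
        assert len(out) == 0 and "gene_id" in out.columns

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(5)
        cand = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(40)],
             "delta_meth": 0.1, "log2fc": -1.0, "n_dmrs": 1}
        )
        core = {f"P{j}": [f"g{i}" for i in rng.choice(60, 10, replace=False)]
                for j in range(4)}
        out = im.hub_genes(cand, core)
        expected = set(cand["gene_id"]) & {g for v in core.values() for g in v}
        assert set(out["gene_id"]) == expected


class TestGenomewideScan:
    def _de(self, genes, lfcs, padj=0.01):
        return pd.DataFrame(
            {"gene_id": genes, "log2fc": lfcs, "p_value": padj, "p_adj": padj}
        )

    def test_all_negative_toy_and_r_squared(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.06, 0.4, 20)
        y = -2 * x - 0.5
        deltas = pd.Series(x, index=[f"g{i}" for i in range(20)])
        de = self._de([f"g{i}" for i in range(20)], y)
        out = im.genomewide_meth_expr_scan(deltas, de)
        assert out["counts"]["negative"] == 20
        assert out["counts"]["positive"] == 0
        expected_r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert out["r_squared"] == pytest.approx(expected_r2, abs=1e-12)

    def test_loose_thresholds_classify_every_gene(self):
        deltas = pd.Series({"a": 0.2, "b": -0.1, "c": 0.3})
        de = self._de(["a", "b", "c"], [1.0, 1.0, -1.0], padj=0.5)
        out = im.genomewide_meth_expr_scan(deltas, de, min_delta=0.0, padj_max=1.0)
        assert out["counts"]["other"] == 0
        assert sum(out["counts"].values()) == 3

    def test_label_counts_sum_to_measured_genes(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(60)]
        deltas = pd.Series(rng.uniform(-0.3, 0.3, 60), index=genes)
        de = self._de(genes, rng.normal(0, 2, 60), padj=rng.random(60))
        out = im.genomewide_meth_expr_scan(deltas, de)
        assert sum(out["counts"].values()) == out["n"] == 60
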