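import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methexp import dmr as dmod
from methexp.simulate import SimulationConfig, simulate_study


def _cx(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"])


def _dmr_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "meth_control", "meth_drought",
                 "delta", "p_value", "genotype_id", "group"],
    )


class TestCallCandidateDmrs:
    def test_identical_conditions_yield_nothing(self):
        rows = [("A01", p, "+", "CHH", 5, 10) for p in range(1, 2000, 9)]
        out = dmod.call_candidate_dmrs(_cx(rows), _cx(rows))
        assert len(out) == 0

    def test_extreme_window_called_with_unit_delta(self):
        ctrl = [("A01", p, "+", "CHH", 0, 100) for p in range(1, 200, 10)]
        drt = [("A01", p, "+", "CHH", 100, 100) for p in range(1, 200, 10)]
        out = dmod.call_candidate_dmrs(_cx(ctrl), _cx(drt))
        assert len(out) == 1
        assert out.iloc[0].delta == pytest.approx(1.0)

    def test_empty_input_gives_empty_output(self):
        out = dmod.call_candidate_dmrs(_cx([]), _cx([]))
        assert len(out) == 0

    def test_window_smaller_than_step_rejected(self):
        with pytest.raises(ValueError):
            dmod.call_candidate_dmrs(_cx([]), _cx([]), window=50, step=200)

    def test_null_per_window_false_positive_rate_calibrated(self):
        # genotype-shared propensities: control vs drought differences are
        # pure binomial noise, so the window test should reject ~alpha
        rates = []
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed, n_genes=16, chrom_length=60_000,
                planted_dmr_spec=[], planted_deg_spec=[], planted_negreg_spec=[],
            )
            study = simulate_study(cfg)
            _, ws = dmod.call_candidate_dmrs(
                study.pooled_cx("S01", "control"),
                study.pooled_cx("S01", "drought"),
                return_window_stats=True,
            )
            rates.append((ws["p_value"] < 0.05).mean())
        assert np.mean(rates) <= 0.05 * 1.5


class TestFilterSignificant:
    def test_context_thresholds_are_strict(self):
        rows = [
            ("A01", 0, 100, "CG", 0.1, 0.31, 0.21, 0.01, "g", "sensitive"),
            ("A01", 0, 100, "CG", 0.1, 0.30, 0.20, 0.01, "g", "sensitive"),
            ("A01", 0, 100, "CHG", 0.1, 0.26, 0.16, 0.01, "g", "sensitive"),
            ("A01", 0, 100, "CHH", 0.3, 0.04, -0.26, 0.01, "g", "sensitive"),
            ("A01", 0, 100, "CHH", 0.3, 0.05, -0.25, 0.01, "g", "sensitive"),
        ]
        out = dmod.filter_significant(_dmr_frame(rows))
        assert list(out.delta.round(2)) == [0.21, 0.16, -0.26]

    def test_unknown_context_rejected(self):
        bad = _dmr_frame([("A01", 0, 100, "CNN", 0, 0.5, 0.5, 0.01, "g", "sensitive")])
        with pytest.raises(ValueError, match="context"):
            dmod.filter_significant(bad)

    def test_matches_brute_force_and_is_idempotent(self):
        rng = np.random.default_rng(4)
        ctxs = rng.choice(["CG", "CHG", "CHH"], 300)
        deltas = rng.uniform(-0.5, 0.5, 300)
        rows = [("A01", i, i + 50, c, 0.0, d, d, 0.01, "g", "sensitive")
                for i, (c, d) in enumerate(zip(ctxs, deltas))]
        df = _dmr_frame(rows)
        out = dmod.filter_significant(df)
        thr = {"CG": 0.20, "CHG": 0.15, "CHH": 0.25}
        expected = {i for i, (c, d) in enumerate(zip(ctxs, deltas)) if abs(d) > thr[c]}
        assert set(out["start"]) == expected
        pd.testing.assert_frame_equal(dmod.filter_significant(out), out)


class TestMergeConserved:
    def _frame(self, intervals, genotypes=None, deltas=None, context="CHH"):
        n = len(intervals)
        genotypes = genotypes or [f"g{i}" for i in range(n)]
        deltas = deltas if deltas is not None else [0.3] * n
        rows = [("A01", s, e, context, 0.0, d, d, 0.01, g, "sensitive")
                for (s, e), g, d in zip(intervals, genotypes, deltas)]
        return _dmr_frame(rows)

    def test_gap_within_limit_merges(self):
        out = dmod.merge_conserved(self._frame([(100, 200), (250, 300)]))
        assert len(out) == 1
        assert (out.iloc[0].start, out.iloc[0].end) == (100, 300)

    def test_gap_boundary_inclusive_at_100(self):
        merged = dmod.merge_conserved(self._frame([(100, 200), (300, 400)]))
        assert len(merged) == 1
        not_merged = dmod.merge_conserved(self._frame([(100, 200), (301, 400)]))
        assert len(not_merged) == 2

    def test_direction_and_support(self):
        df = self._frame(
            [(100, 200), (150, 260), (240, 330)],
            genotypes=["g1", "g2", "g1"],
            deltas=[0.3, 0.4, 0.35],
        )
        out = dmod.merge_conserved(df)
        assert len(out) == 1
        row = out.iloc[0]
        assert row.n_support == 2  # distinct genotypes
        assert row.direction == "hyper"
        # per-genotype means: g1 -> 0.325, g2 -> 0.4
        assert row.mean_delta == pytest.approx((0.325 + 0.4) / 2)

    def test_mixed_direction(self):
        df = self._frame([(100, 200), (150, 250)], deltas=[0.3, -0.3])
        assert dmod.merge_conserved(df).iloc[0].direction == "mixed"

    def test_multiple_groups_rejected(self):
        df = self._frame([(0, 100)])
        df.loc[0, "group"] = "tolerant"
        both = pd.concat([df, self._frame([(500, 600)])])
        with pytest.raises(ValueError, match="single phenotype group"):
            dmod.merge_conserved(both)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 5000), min_size=1, max_size=60), st.integers(0, 3))
    def test_idempotent_and_disjoint_on_random_intervals(self, starts, seed):
        rng = np.random.default_rng(seed)
        intervals = [(s, s + int(rng.integers(10, 400))) for s in sorted(starts)]
        df = self._frame(intervals)
        merged = dmod.merge_conserved(df)
        # disjoint beyond the merge gap
        sub = merged.sort_values("start")
        gaps = sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]
        assert (gaps > 100).all()
        # idempotence: re-merging the merged regions changes nothing
        again = dmod.merge_conserved(
            merged.rename(columns={"mean_delta": "delta", "genotype_ids": "genotype_id"})
        )
        assert list(again["start"]) == list(merged["start"])
        assert list(again["end"]) == list(merged["end"])


class TestSupportFilter:
    def test_boundary_at_three(self):
        df = pd.DataFrame(
            {"chrom": ["A01"] * 2, "start": [0, 10], "end": [5, 20],
             "context": ["CG"] * 2, "group": ["sensitive"] * 2,
             "direction": ["hyper"] * 2, "n_support": [3, 2],
             "mean_delta": [0.3, 0.3], "genotype_ids": ["a,b,c", "a,b"]}
        )
        out = dmod.support_filter(df, min_genotypes=3)
        assert list(out["n_support"]) == [3]

    def test_min_one_is_identity(self):
        df = pd.DataFrame(
            {"chrom": ["A01"], "start": [0], "end": [5], "context": ["CG"],
             "group": ["s"], "direction": ["hyper"], "n_support": [1],
             "mean_delta": [0.3], "genotype_ids": ["a"]}
        )
        pd.testing.assert_frame_equal(dmod.support_filter(df, min_genotypes=1), df)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        supports = rng.integers(1, 7, 50)
        df = pd.DataFrame(
            {"chrom": "A01", "start": np.arange(50) * 1000,
             "end": np.arange(50) * 1000 + 100, "context": "CHH", "group": "s",
             "direction": "hyper", "n_support": supports, "mean_delta": 0.3,
             "genotype_ids": "x"}
        )
        out = dmod.support_filter(df, min_genotypes=4)
        assert set(out["start"]) == {s for s, n in zip(df["start"], supports) if n >= 4}


class TestAnnotateFeature:
    genes = pd.DataFrame(
        [("gp", "A01", 10_000, 12_000, "+"), ("gm", "A01", 30_000, 32_000, "-")],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )

    def _conserved(self, start, end, chrom="A01"):
        return pd.DataFrame(
            {"chrom": [chrom], "start": [start], "end": [end], "context": ["CHH"],
             "group": ["s"], "direction": ["hyper"], "n_support": [3],
             "mean_delta": [0.3], "genotype_ids": ["x"]}
        )

    def test_inside_gene_body(self):
        assert dmod.annotate_feature(self._conserved(10_500, 10_700), self.genes)[0] == "gene_body"

    def test_minus_strand_upstream_is_right_of_gene(self):
        # 500 bp 5' of the minus-strand gene means past its end coordinate
        lab = dmod.annotate_feature(self._conserved(32_400, 32_600), self.genes)
        assert lab[0] == "upstream2k"
        lab2 = dmod.annotate_feature(self._conserved(29_000, 29_200), self.genes)
        assert lab2[0] == "downstream2k"

    def test_far_region_is_intergenic(self):
        assert dmod.annotate_feature(self._conserved(20_000, 20_100), self.genes)[0] == "intergenic"

    def test_tss_spanning_region_takes_gene_body_precedence(self):
        assert dmod.annotate_feature(self._conserved(9_900, 10_100), self.genes)[0] == "gene_body"


class TestDmrCountTable:
    # study bookkeeping: per-(group, context) counts at three tiers
    table = pd.DataFrame(
        {
            "conserved": [1651, 1100, 5914, 1850, 1099, 6567],
            "significant": [1362, 918, 4894, 1515, 911, 5552],
            "associated_genes": [1311, 867, 4531, 1412, 849, 5078],
        },
        index=pd.MultiIndex.from_product(
            [["tolerant", "sensitive"], ["CG", "CHG", "CHH"]], names=["group", "context"]
        ),
    )

    def test_chh_fractions_of_significant_dmrs(self):
        out = dmod.dmr_count_table(self.table)
        assert out["chh_fraction"]["significant"]["sensitive"] == 69.6
        assert out["chh_fraction"]["significant"]["tolerant"] == 68.2

    def test_sensitive_over_tolerant_excess_per_tier(self):
        out = dmod.dmr_count_table(self.table)
        assert out["excess_pct"]["conserved"] == 9.82
        assert out["excess_pct"]["significant"] == 11.21
        assert out["excess_pct"]["associated_genes"] == 9.39

    def test_equal_groups_have_zero_excess(self):
        eq = self.table.copy()
        eq.loc["sensitive"] = eq.loc["tolerant"].to_numpy()
        out = dmod.dmr_count_table(eq)
        assert all(v == 0.0 for v in out["excess_pct"].values())

    def test_zero_tolerant_total_rejected(self):
        z = self.table.copy()
        z.loc["tolerant", "conserved"] = 0
        with pytest.raises(ValueError, match="undefined"):
            dmod.dmr_count_table(z)


class TestChromosomeDensity:
    def _conserved(self, chroms):
        return pd.DataFrame(
            {"chrom": chroms, "start": 0, "end": 100, "context": "CHH", "group": "s",
             "direction": "hyper", "n_support": 3, "mean_delta": 0.3, "genotype_ids": "x"}
        )

    def test_density_per_megabase(self):
        out = dmod.chromosome_density(self._conserved(["A01"] * 10), {"A01": 1_000_000})
        assert out.iloc[0].density_per_mb == pytest.approx(10.0)

    def test_invariant_to_input_order(self):
        df = self._conserved(["A01", "C01", "A01"])
        a = dmod.chromosome_density(df, {"A01": 1e6, "C01": 1e6})
        b = dmod.chromosome_density(df.iloc[::-1], {"A01": 1e6, "C01": 1e6})
        pd.testing.assert_frame_equal(a, b)

    def test_missing_length_named(self):
        with pytest.raises(ValueError, match="C01"):
            dmod.chromosome_density(self._conserved(["C01"]), {"A01": 1e6})

    def test_c_biased_planting_gives_higher_c_density(self, tiny_study):
        from methexp import pipeline

        _, _, supported = pipeline.group_conserved_dmrs(tiny_study, "sensitive")
        out = dmod.chromosome_density(supported, tiny_study.chrom_lengths)
        # sanity on subgenome attribution rather than planted bias (layout is
        # uniform here): every chromosome is attributed, densities non-negative
        assert set(out["subgenome"]) <= {"A", "C"}
        assert (out["density_per_mb"] >= 0).all()
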