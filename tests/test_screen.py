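"""Unit and property tests for ortholog pairing and the correlation screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from conftest import textbook_pearson
from orthoscreen.containers import OrthologMap, ReferenceSpec, StageProfile
from orthoscreen.normalize import cpm_log2, stage_mean_profile, zscale_profile
from orthoscreen.screen import (
    pair_by_name,
    passing_gene_list,
    pearson_r,
    screen,
    screen_summary,
)


class TestPairByName:
    def test_paralog_suffix_convention_yields_one_to_many(self):
        omap = pair_by_name(["Sox9"], ["sox9a", "sox9b"])
        assert set(omap.pairs) == {("Sox9", "sox9a"), ("Sox9", "sox9b")}

    def test_case_insensitive_identity(self):
        omap = pair_by_name(["Abc1"], ["abc1"])
        assert omap.pairs == [("Abc1", "abc1")]

    def test_no_match_gives_empty_map(self):
        omap = pair_by_name(["X"], ["y"])
        assert omap.pairs == []

    def test_table_mode_drops_rows_with_absent_genes(self, caplog):
        table = pd.DataFrame(
            {"gene_a": ["A", "A", "ghost"], "gene_b": ["a1", "ghost", "a1"]}
        )
        with caplog.at_level("WARNING", logger="orthoscreen"):
            omap = pair_by_name(["A"], ["a1"], mode="table", table=table)
        assert omap.pairs == [("A", "a1")]
        assert any("2" in m for m in caplog.messages)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            pair_by_name([], ["a"])


class TestPearsonR:
    def test_self_correlation_is_one(self):
        assert pearson_r([1.0, 2.0, 5.0, 3.0], [1.0, 2.0, 5.0, 3.0]) == 1.0

    def test_exact_reversal_is_minus_one(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == -1.0

    def test_frozen_textbook_example(self):
        # cov/sd ratio computed by hand: 12 / sqrt(10 * 16)
        assert pearson_r([1, 2, 3, 4, 5], [1, 2, 2, 4, 6]) == pytest.approx(
            12 / math.sqrt(160), abs=1e-15
        )

    def test_zero_variance_flagged_undefined(self):
        assert math.isnan(pearson_r([1, 1, 1], [1, 2, 3]))

    def test_length_errors(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2, 3, 4])

    def test_matches_independent_textbook_formula(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert abs(pearson_r(x, y) - textbook_pearson(x, y)) <= 1e-12

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_shift_scale_invariant(self, xs):
        x = np.asarray(xs)
        # avoid degenerate spreads where adding the shift rounds x constant
        assume(np.ptp(x) > 1e-6)
        y = np.arange(len(x), dtype=float)
        r = pearson_r(x, y)
        assert -1.0 <= r <= 1.0
        assert pearson_r(3.0 * x + 7.0, y) == pytest.approx(r, abs=1e-9)


class TestScreen:
    @staticmethod
    def _toy():
        stages_a = list("abcde")
        profiles_a = StageProfile(
            pd.DataFrame(
                {
                    "Ref": [0, 1, 2, 3, 4],
                    "Hit": [0.1, 1.0, 2.2, 2.9, 4.1],
                    "Miss": [4, 3, 2, 1, 0],
                    "Flat": [1, 1, 1, 1, 1],
                },
                index=stages_a,
            ).T
        )
        profiles_b = StageProfile(
            pd.DataFrame(
                {
                    "ref": [0, 2, 4, 4, 4],
                    "hitb": [0.2, 2.1, 3.8, 4.0, 4.2],
                    "hita": [4, 4, 2, 1, 0],
                    "miss": [1, 0, 1, 0, 1],
                    "flat": [2, 2, 2, 2, 2],
                },
                index=stages_a,
            ).T
        )
        omap = OrthologMap(
            [
                ("Ref", "ref"),
                ("Hit", "hitb"),
                ("Hit", "hita"),
                ("Miss", "miss"),
                ("Flat", "flat"),
            ]
        )
        return profiles_a, profiles_b, omap

    def test_reference_pair_trivially_passes_with_r_one(self):
        pa, pb, omap = self._toy()
        rec = screen(pa, pb, omap, ReferenceSpec("Ref", "ref", 0.7))
        ref_row = rec[(rec.gene_a == "Ref") & (rec.gene_b == "ref")].iloc[0]
        assert ref_row.r_a == 1.0 and ref_row.r_b == 1.0 and ref_row.pass_both

    def test_one_to_many_pairs_screened_independently(self):
        # the reference-tracking duplicate passes, the divergent one fails
        pa, pb, omap = self._toy()
        rec = screen(pa, pb, omap, ReferenceSpec("Ref", "ref", 0.7)).set_index(
            ["gene_a", "gene_b"]
        )
        assert rec.loc[("Hit", "hitb"), "pass_both"]
        assert not rec.loc[("Hit", "hita"), "pass_both"]

    def test_constant_gene_fails_with_undefined_flag(self):
        pa, pb, omap = self._toy()
        rec = screen(pa, pb, omap, ReferenceSpec("Ref", "ref", 0.7)).set_index(
            ["gene_a", "gene_b"]
        )
        row = rec.loc[("Flat", "flat")]
        assert math.isnan(row.r_a) and math.isnan(row.r_b)
        assert not row.pass_both

    def test_records_sorted_by_min_r_then_names(self):
        pa, pb, omap = self._toy()
        rec = screen(pa, pb, omap, ReferenceSpec("Ref", "ref", 0.7))
        min_r = np.fmin(rec.r_a.fillna(-2), rec.r_b.fillna(-2)).to_numpy()
        assert np.all(np.diff(min_r) <= 1e-12)

    def test_missing_reference_gene_raises_naming_species(self):
        pa, pb, omap = self._toy()
        with pytest.raises(ValueError, match="species-A"):
            screen(pa, pb, omap, ReferenceSpec("NotThere", "ref", 0.7))
        with pytest.raises(ValueError, match="species-B"):
            screen(pa, pb, omap, ReferenceSpec("Ref", "notthere", 0.7))

    def test_pass_both_is_conjunction(self):
        pa, pb, omap = self._toy()
        rec = screen(pa, pb, omap, ReferenceSpec("Ref", "ref", 0.7))
        assert (rec.pass_both == (rec.pass_a & rec.pass_b)).all()

    def test_threshold_monotonicity(self):
        pa, pb, omap = self._toy()
        passing = {}
        for t in (0.3, 0.5, 0.7, 0.9):
            rec = screen(pa, pb, omap, ReferenceSpec("Ref", "ref", t))
            passing[t] = set(map(tuple, rec.loc[rec.pass_both, ["gene_a", "gene_b"]].values))
        assert passing[0.9] <= passing[0.7] <= passing[0.5] <= passing[0.3]


class TestScreenOnSimulatedData:
    def test_noiseless_recovery_is_exact(self, noiseless_sim, noiseless_config):
        cfg = noiseless_config
        sim = noiseless_sim
        prof_a = stage_mean_profile(cpm_log2(sim.counts_a), sim.counts_a.samples, cfg.stages_a)
        prof_b = stage_mean_profile(cpm_log2(sim.counts_b), sim.counts_b.samples, cfg.stages_b)
        rec = screen(prof_a, prof_b, sim.ortholog_map, ReferenceSpec("Sox9", "sox9b", 0.7))
        got = set(map(tuple, rec.loc[rec.pass_both, ["gene_a", "gene_b"]].values))
        truth = sim.truth
        want = set(
            map(
                tuple,
                truth.loc[
                    truth.label.isin(["reference", "planted_correlated"]),
                    ["gene_a", "gene_b"],
                ].values,
            )
        )
        assert got == want

    def test_verdicts_invariant_to_scaling(self, small_sim, small_config):
        cfg = small_config
        sim = small_sim
        prof_a = stage_mean_profile(cpm_log2(sim.counts_a), sim.counts_a.samples, cfg.stages_a)
        prof_b = stage_mean_profile(cpm_log2(sim.counts_b), sim.counts_b.samples, cfg.stages_b)
        ref = ReferenceSpec("Sox9", "sox9b", 0.7)
        raw = screen(prof_a, prof_b, sim.ortholog_map, ref)
        scaled = screen(zscale_profile(prof_a), zscale_profile(prof_b), sim.ortholog_map, ref)
        pd.testing.assert_series_equal(raw.pass_both, scaled.pass_both)
        pd.testing.assert_frame_equal(raw[["gene_a", "gene_b"]], scaled[["gene_a", "gene_b"]])


class TestPassingGeneList:
    def test_deduplicates_shared_side_gene(self):
        rec = pd.DataFrame(
            {
                "gene_a": ["X", "X", "Y"],
                "gene_b": ["xa", "xb", "y"],
                "pass_both": [True, True, False],
            }
        )
        assert passing_gene_list(rec, "a") == ["X"]
        assert passing_gene_list(rec, "b") == ["xa", "xb"]

    def test_empty_when_nothing_passes(self):
        rec = pd.DataFrame({"gene_a": ["X"], "gene_b": ["x"], "pass_both": [False]})
        assert passing_gene_list(rec, "a") == []

    def test_summary_counts_both_pairs_and_unique_genes(self):
        rec = pd.DataFrame(
            {
                "gene_a": ["X", "X"],
                "gene_b": ["xa", "xb"],
                "r_a": [0.9, 0.9],
                "r_b": [0.8, 0.85],
                "pass_a": [True, True],
                "pass_b": [True, True],
                "pass_both": [True, True],
            }
        )
        s = screen_summary(rec)
        assert s["n_pass_both"] == 2
        assert s["n_pass_both_genes_a"] == 1
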