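"""Blank-based contaminant classification, subtraction, and depth filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otukit.core_io import AnalysisConfig, CountTable, TaxonomyTable, align_study
from otukit.decontam import (
    DecontamDecision,
    OtuBlankStats,
    apply_decontam,
    blank_prevalence,
    classify_contaminants,
    dispersion_score,
    filter_low_depth,
    run_decontam,
)

from .conftest import make_metadata, random_table


class TestDispersionScore:
    def test_all_zero_vector(self):
        assert dispersion_score([0, 0, 0]) == 0.0

    def test_singleton_has_zero_sd(self):
        assert dispersion_score([7]) == pytest.approx(7.0)

    def test_two_point_formula(self):
        # independent arithmetic: GM = exp((ln51 + ln71)/2) - 1, SD over {50,70}
        gm = np.exp((np.log(51) + np.log(71)) / 2) - 1
        sd = np.std([50.0, 70.0], ddof=1)
        assert dispersion_score([50, 70]) == pytest.approx(gm + sd, rel=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            dispersion_score([])


class TestBlankPrevalence:
    def test_half_of_two_blanks(self):
        t = CountTable(("o1",), ("b1", "b2"), np.array([[5, 0]]))
        assert blank_prevalence(t, ["b1", "b2"])["o1"] == 0.5

    def test_absent_from_all_blanks(self):
        t = CountTable(("o1",), ("b1", "b2"), np.array([[0, 0]]))
        assert blank_prevalence(t, ["b1", "b2"])["o1"] == 0.0

    def test_matches_brute_force(self, rng):
        t = random_table(rng, n_otus=20, n_samples=8, max_count=3)
        blanks = list(t.sample_ids[:4])
        prev = blank_prevalence(t, blanks)
        for i, otu in enumerate(t.otu_ids):
            manual = sum(t.column(b)[i] > 0 for b in blanks) / len(blanks)
            assert prev[otu] == manual

    def test_empty_blank_set_instructs_skip(self, rng):
        t = random_table(rng, 3, 3)
        with pytest.raises(ValueError, match="skip"):
            blank_prevalence(t, [])


def _mini_table(blank_counts, specimen_counts):
    """Single-OTU table over 2 blanks and 3 specimens."""
    n_b, n_s = len(blank_counts), len(specimen_counts)
    ids = [f"b{i}" for i in range(n_b)] + [f"s{i}" for i in range(n_s)]
    return CountTable(("otu",), tuple(ids), np.array([blank_counts + specimen_counts]))


class TestClassify:
    def test_blank_dominated_otu_removed(self, cfg):
        t = _mini_table([50, 70], [2, 0, 1])
        (d,) = classify_contaminants(t, ["b0", "b1"], ["s0", "s1", "s2"], cfg)
        assert d.action == "remove"
        assert d.stats.blank_dispersion > d.stats.sample_dispersion

    def test_prevalence_threshold_is_strict(self, cfg):
        t = _mini_table([50, 0], [0, 0, 0])  # exactly 50% of blanks
        (d,) = classify_contaminants(t, ["b0", "b1"], ["s0", "s1", "s2"], cfg)
        assert d.action == "keep"

    def test_abundant_in_specimens_subtracted(self, cfg):
        t = _mini_table([3, 2], [500, 800, 650])
        (d,) = classify_contaminants(t, ["b0", "b1"], ["s0", "s1", "s2"], cfg)
        assert d.action == "subtract"

    def test_disjointness_required(self, cfg):
        t = _mini_table([1, 1], [1, 1, 1])
        with pytest.raises(ValueError, match="disjoint"):
            classify_contaminants(t, ["b0"], ["b0", "s0"], cfg)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_decision_partition(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_otus=15, n_samples=8, max_count=40)
        cfg = AnalysisConfig()
        blanks, specimens = list(t.sample_ids[:3]), list(t.sample_ids[3:])
        decisions = classify_contaminants(t, blanks, specimens, cfg)
        assert sorted(d.otu_id for d in decisions) == sorted(t.otu_ids)
        for d in decisions:
            if d.action in ("remove", "subtract"):
                assert d.stats.blank_prevalence > cfg.blank_prevalence_threshold


class TestApply:
    def _decision(self, otu, action, background=0.0):
        return DecontamDecision(otu, action, OtuBlankStats(otu, 1.0, 0.0, 0.0, background))

    def test_subtraction_floors_at_zero(self):
        t = CountTable(("otu",), ("s0", "s1"), np.array([[100, 8]]))
        out = apply_decontam(t, [self._decision("otu", "subtract", 10.5)], ["s0", "s1"])
        np.testing.assert_array_equal(out.counts, [[89, 0]])

    def test_all_keep_is_identity_on_specimens(self, rng):
        t = random_table(rng, 6, 5)
        decisions = [self._decision(o, "keep") for o in t.otu_ids]
        out = apply_decontam(t, decisions, list(t.sample_ids[:3]))
        np.testing.assert_array_equal(out.counts, t.counts[:, :3])

    def test_remove_all_annihilates(self, rng):
        t = random_table(rng, 6, 5)
        decisions = [self._decision(o, "remove") for o in t.otu_ids]
        out = apply_decontam(t, decisions, list(t.sample_ids))
        assert out.n_otus == 0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_never_increases_counts_never_negative(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, 10, 6, max_count=50)
        actions = rng.choice(["keep", "remove", "subtract"], size=10)
        bgs = rng.uniform(0, 30, size=10)
        decisions = [
            self._decision(o, a, b) for o, a, b in zip(t.otu_ids, actions, bgs)
        ]
        out = apply_decontam(t, decisions, list(t.sample_ids))
        assert out.counts.min() >= 0 if out.counts.size else True
        kept = {o: i for i, o in enumerate(t.otu_ids)}
        for i, otu in enumerate(out.otu_ids):
            assert (out.counts[i] <= t.counts[kept[otu]]).all()


class TestDepthFilter:
    def test_strict_under_1000_boundary(self):
        t = CountTable(
            ("o1",), ("a", "b", "c"), np.array([[999, 1000, 12000]])
        )
        out, dropped = filter_low_depth(t, 1000)
        assert dropped == {"a": 999}
        assert out.sample_ids == ("b", "c")

    def test_zero_threshold_is_identity(self, rng):
        t = random_table(rng, 4, 5)
        out, dropped = filter_low_depth(t, 0)
        assert dropped == {}
        assert out.sample_ids == t.sample_ids

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), cutoff=st.integers(0, 400))
    def test_matches_brute_force(self, seed, cutoff):
        rng = np.random.default_rng(seed)
        t = random_table(rng, 8, 6, max_count=60)
        expected = [s for s in t.sample_ids if t.column(s).sum() >= cutoff]
        if not expected:
            with pytest.raises(ValueError):
                filter_low_depth(t, cutoff)
        else:
            out, _ = filter_low_depth(t, cutoff)
            assert list(out.sample_ids) == expected

    def test_all_dropped_raises(self):
        t = CountTable(("o1",), ("a",), np.array([[5]]))
        with pytest.raises(ValueError, match="inspect"):
            filter_low_depth(t, 10)


def _two_stratum_bundle():
    """Stool stratum with a spiked contaminant; milk stratum clean."""
    otus = ("real1", "real2", "cont")
    samples = ("st1", "st2", "bkS1", "bkS2", "mk1", "mk2", "bkM1", "bkM2")
    counts = np.array(
        [
            [2000, 1800, 0, 0, 1500, 1600, 0, 0],
            [1500, 1700, 2, 1, 1400, 1500, 1, 0],
            [3, 1, 80, 95, 1200, 1300, 0, 0],  # contaminant in stool only
        ]
    )
    table = CountTable(otus, samples, counts)
    meta = make_metadata(
        [
            {"sample_id": "st1", "sample_type": "child_stool", "batch": "stool"},
            {"sample_id": "st2", "sample_type": "child_stool", "batch": "stool"},
            {"sample_id": "bkS1", "sample_type": "blank", "batch": "stool"},
            {"sample_id": "bkS2", "sample_type": "blank", "batch": "stool"},
            {"sample_id": "mk1", "sample_type": "breast_milk", "batch": "breast_milk"},
            {"sample_id": "mk2", "sample_type": "breast_milk", "batch": "breast_milk"},
            {"sample_id": "bkM1", "sample_type": "blank", "batch": "breast_milk"},
            {"sample_id": "bkM2", "sample_type": "blank", "batch": "breast_milk"},
        ]
    )
    return align_study(table, meta, TaxonomyTable({}))


class TestRunDecontam:
    def test_strata_are_independent(self, cfg):
        bundle = _two_stratum_bundle()
        strata = {
            "stool": (["bkS1", "bkS2"], ["st1", "st2"]),
            "breast_milk": (["bkM1", "bkM2"], ["mk1", "mk2"]),
        }
        cleaned, reports = run_decontam(bundle, strata, cfg)
        stool = {r.stratum: r for r in reports}["stool"]
        milk = {r.stratum: r for r in reports}["breast_milk"]
        assert {d.otu_id: d.action for d in stool.decisions}["cont"] == "remove"
        # in milk the same OTU is abundant in specimens and absent from blanks
        assert {d.otu_id: d.action for d in milk.decisions}["cont"] == "keep"
        # removed from stool columns, retained in milk columns
        df = cleaned.to_dataframe()
        assert df.loc["cont", ["st1", "st2"]].sum() == 0
        assert df.loc["cont", ["mk1", "mk2"]].sum() > 0

    def test_single_stratum_equals_manual_composition(self, cfg):
        bundle = _two_stratum_bundle()
        strata = {"stool": (["bkS1", "bkS2"], ["st1", "st2"])}
        cleaned, _ = run_decontam(bundle, strata, cfg)
        decisions = classify_contaminants(
            bundle.table, ["bkS1", "bkS2"], ["st1", "st2"], cfg
        )
        manual = apply_decontam(bundle.table, decisions, ["st1", "st2"])
        manual, _ = filter_low_depth(manual, cfg.min_sample_depth)
        df, mf = cleaned.to_dataframe(), manual.to_dataframe()
        mf = mf.loc[mf.sum(axis=1) > 0]
        assert df.sort_index().equals(mf.sort_index())

    def test_no_blank_stratum_passes_through(self, cfg):
        bundle = _two_stratum_bundle()
        strata = {"milk": ([], ["mk1", "mk2"])}
        with pytest.warns(UserWarning, match="no blanks"):
            cleaned, reports = run_decontam(bundle, strata, cfg)
        assert all(d.action == "keep" for d in reports[0].decisions)
        df = cleaned.to_dataframe()
        src = bundle.table.to_dataframe()[["mk1", "mk2"]]
        src = src.loc[src.sum(axis=1) > 0]
        assert df.sort_index().equals(src.sort_index())

    def test_rerun_without_blanks_is_identity(self, cfg):
        """Decontaminating an already-cleaned table (no blanks) changes nothing."""
        bundle = _two_stratum_bundle()
        strata = {
            "stool": (["bkS1", "bkS2"], ["st1", "st2"]),
            "breast_milk": (["bkM1", "bkM2"], ["mk1", "mk2"]),
        }
        cleaned, _ = run_decontam(bundle, strata, cfg)
        meta2 = make_metadata(
            [
                {"sample_id": s, "sample_type": "child_stool", "batch": "stool"}
                for s in cleaned.sample_ids
            ]
        )
        bundle2 = align_study(cleaned, meta2, TaxonomyTable({}))
        with pytest.warns(UserWarning):
            cleaned2, _ = run_decontam(
                bundle2, {"stool": ([], list(cleaned.sample_ids))}, cfg
            )
        assert cleaned2.to_dataframe().sort_index().equals(
            cleaned.to_dataframe().sort_index()
        )
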