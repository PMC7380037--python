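"""Refinement-cascade stages: rules, boundaries, provenance accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import trophodiet.filtering as F
from trophodiet.filtering import FilterConfig, FilterError
from trophodiet.table import MotuTable, ValidationError

from conftest import build_table


def cascade_fixture():
    """Hand-designed table exercising every cascade stage.

    Expected behaviour (worked through by hand, cell by cell):

    * mA1 + mA2 are both Carcinus maenas -> merged into mA1 (higher
      best identity), summed cell-wise.
    * mTag has one 6-read cell against a 2,106-read row total: below the
      1% tag-jump threshold (21.06) -> zeroed.
    * mBact is kingdom Bacteria -> removed (150 reads).
    * mLow has cells of 4 and 5 reads: the 4 is zeroed, the 5 kept.
    * mCtrl has 5 of its 40 reads (12.5% > 10%) in the negative
      control -> removed; the control column is then consumed.
    * mFocal is the consumer (Crangon crangon) -> removed; per-sample
      focal proportions recorded.
    * st2 then holds 905 diet reads < 1,000 -> dropped.
    """
    return build_table(
        counts={
            "mA1":   {"st1": 1200, "st2": 600, "sed1": 40, "nc1": 0},
            "mA2":   {"st1": 100,  "st2": 0,   "sed1": 0,  "nc1": 0},
            "mTag":  {"st1": 2000, "st2": 6,   "sed1": 100, "nc1": 0},
            "mBact": {"st1": 50,   "st2": 50,  "sed1": 50, "nc1": 0},
            "mLow":  {"st1": 4,    "st2": 5,   "sed1": 0,  "nc1": 0},
            "mCtrl": {"st1": 30,   "st2": 5,   "sed1": 0,  "nc1": 5},
            "mFocal": {"st1": 1000, "st2": 1500, "sed1": 30, "nc1": 0},
            "mPrey": {"st1": 1500, "st2": 300, "sed1": 700, "nc1": 0},
        },
        taxonomy={
            "mA1": dict(rank="species", kingdom="Eukaryota",
                        phylum="Arthropoda", species="Carcinus maenas",
                        best_identity=1.0),
            "mA2": dict(rank="species", kingdom="Eukaryota",
                        phylum="Arthropoda", species="Carcinus maenas",
                        best_identity=0.9),
            "mTag": dict(rank="species", kingdom="Eukaryota",
                         phylum="Annelida", species="Hediste diversicolor"),
            "mBact": dict(rank="phylum", kingdom="Bacteria",
                          phylum="Proteobacteria"),
            "mLow": dict(rank="genus", kingdom="Eukaryota",
                         phylum="Mollusca", genus="Mytilus"),
            "mCtrl": dict(rank="unassigned"),
            "mFocal": dict(rank="species", kingdom="Eukaryota",
                           phylum="Arthropoda", species="Crangon crangon"),
            "mPrey": dict(rank="species", kingdom="Eukaryota",
                          phylum="Arthropoda", species="Corophium volutator"),
        },
        samples={
            "st1": dict(sample_type="stomach", site="A"),
            "st2": dict(sample_type="stomach", site="B"),
            "sed1": dict(sample_type="sediment", site="A"),
            "nc1": dict(sample_type="negative_control", site=pd.NA,
                        estuary=pd.NA),
        },
    )


class TestMergeSpeciesMotus:
    def test_same_species_summed_cellwise(self):
        t = build_table(
            counts={"a": {"s1": 10, "s2": 5}, "b": {"s1": 2, "s2": 0}},
            taxonomy={
                "a": dict(rank="species", species="Carcinus maenas",
                          best_identity=1.0),
                "b": dict(rank="species", species="Carcinus maenas",
                          best_identity=0.8),
            },
            samples={"s1": {}, "s2": {}},
        )
        out, rec = F.merge_species_motus(t)
        assert list(out.motu_ids) == ["a"]  # higher best_identity kept
        assert out.counts.loc["a"].tolist() == [12, 5]
        assert out.total_reads() == t.total_reads()
        assert "b" in rec.removed_motus

    def test_genus_level_assignments_not_merged(self):
        t = build_table(
            counts={"a": {"s1": 10}, "b": {"s1": 2}},
            taxonomy={"a": dict(rank="genus", genus="Carcinus"),
                      "b": dict(rank="genus", genus="Carcinus")},
            samples={"s1": {}},
        )
        out, rec = F.merge_species_motus(t)
        assert out.n_motus == 2 and not rec.removed_motus

    def test_distinct_species_identity(self):
        t = build_table(
            counts={"a": {"s1": 10}, "b": {"s1": 2}},
            taxonomy={"a": dict(rank="species", species="Aa bb"),
                      "b": dict(rank="species", species="Cc dd")},
            samples={"s1": {}},
        )
        out, rec = F.merge_species_motus(t)
        assert out.equals(t) and not rec.removed_motus


class TestRenormalizeTagSwitching:
    def test_sub_threshold_cell_zeroed(self):
        t = build_table(
            counts={"m": {"s1": 995, "s2": 5}},
            taxonomy={"m": {}},
            samples={"s1": {}, "s2": {}},
        )
        out, _ = F.renormalize_tag_switching(t, 0.01)
        # 5 < 0.01 * 1000
        assert out.counts.loc["m"].tolist() == [995, 0]

    def test_single_occupied_cell_is_fixed_point(self):
        t = build_table(counts={"m": {"s1": 3, "s2": 0}}, taxonomy={"m": {}},
                        samples={"s1": {}, "s2": {}})
        out, _ = F.renormalize_tag_switching(t, 0.5)
        assert out.counts.loc["m", "s1"] == 3

    def test_cell_exactly_at_threshold_retained(self):
        t = build_table(
            counts={"m": {"s1": 990, "s2": 10}},
            taxonomy={"m": {}},
            samples={"s1": {}, "s2": {}},
        )
        out, _ = F.renormalize_tag_switching(t, 0.01)
        assert out.counts.loc["m", "s2"] == 10  # strict inequality


class TestRemoveContaminants:
    def test_bacterial_kingdom_removed(self, small_table):
        tax = small_table.taxonomy.copy()
        tax.loc["m3", "kingdom"] = "Bacteria"
        t = MotuTable(small_table.counts, tax, small_table.samples)
        out, rec = F.remove_contaminants(
            t, [{"rank": "kingdom", "name": "Bacteria"}]
        )
        assert "m3" not in out.motu_ids and "m3" in rec.removed_motus

    def test_human_blacklist(self):
        t = build_table(
            counts={"h": {"s1": 9}, "p": {"s1": 1}},
            taxonomy={"h": dict(rank="species", species="Homo sapiens"),
                      "p": dict(rank="species", species="Corophium volutator")},
            samples={"s1": {}},
        )
        out, _ = F.remove_contaminants(
            t, [{"rank": "species", "name": "Homo sapiens"}]
        )
        assert list(out.motu_ids) == ["p"]

    def test_empty_rule_list_identity(self, small_table):
        out, rec = F.remove_contaminants(small_table, [])
        assert out.equals(small_table) and not rec.removed_motus

    def test_unknown_taxonomy_field_errors(self, small_table):
        with pytest.raises(ValidationError, match="unknown field"):
            F.remove_contaminants(small_table, [{"rank": "clade", "name": "X"}])


class TestMinReadsFilter:
    def test_four_or_fewer_zeroed_five_kept(self):
        t = build_table(counts={"m": {"s1": 4, "s2": 5}}, taxonomy={"m": {}},
                        samples={"s1": {}, "s2": {}})
        out, _ = F.min_reads_filter(t, 5)
        assert out.counts.loc["m"].tolist() == [0, 5]

    def test_all_low_row_dropped(self):
        t = build_table(
            counts={"m": {"s1": 4, "s2": 3, "s3": 2}, "k": {"s1": 10}},
            taxonomy={"m": {}, "k": {}},
            samples={"s1": {}, "s2": {}, "s3": {}},
        )
        out, rec = F.min_reads_filter(t, 5)
        assert "m" not in out.motu_ids and "m" in rec.removed_motus
        assert rec.reconciles()

    def test_threshold_one_is_identity(self, small_table):
        out, _ = F.min_reads_filter(small_table, 1)
        assert out.equals(small_table)

    def test_motu_mode_keys_on_row_maximum(self):
        t = build_table(
            counts={"m": {"s1": 4, "s2": 3}, "k": {"s1": 5, "s2": 1}},
            taxonomy={"m": {}, "k": {}},
            samples={"s1": {}, "s2": {}},
        )
        out, _ = F.min_reads_filter(t, 5, mode="motu")
        assert list(out.motu_ids) == ["k"]
        assert out.counts.loc["k"].tolist() == [5, 1]  # cells untouched


class TestNegativeControlFilter:
    def _table(self, ctrl_reads, other_reads):
        return build_table(
            counts={"m": {"s1": other_reads, "nc": ctrl_reads},
                    "keep": {"s1": 100, "nc": 0}},
            taxonomy={"m": {}, "keep": {}},
            samples={"s1": {}, "nc": dict(sample_type="negative_control",
                                          site=pd.NA, estuary=pd.NA)},
        )

    def test_above_ten_percent_removed(self):
        out, rec = F.negative_control_filter(self._table(5, 35), 0.10)
        assert "m" not in out.motu_ids  # 5/40 = 12.5%

    def test_exactly_ten_percent_retained(self):
        out, _ = F.negative_control_filter(self._table(10, 90), 0.10)
        assert "m" in out.motu_ids  # strict inequality

    def test_absent_from_controls_retained(self):
        out, _ = F.negative_control_filter(self._table(0, 40), 0.10)
        assert set(out.motu_ids) == {"m", "keep"}

    def test_control_columns_consumed(self):
        out, _ = F.negative_control_filter(self._table(0, 40), 0.10)
        assert "nc" not in out.sample_ids

    def test_no_controls_logged_noop(self, small_table):
        t = small_table.subset(sample_types={"stomach", "sediment"})
        out, rec = F.negative_control_filter(t, 0.10)
        assert out.equals(t) and "skipped" in rec.details["note"]


class TestRemoveFocalTaxa:
    def test_proportion_reported(self):
        t = build_table(
            counts={"f": {"s1": 28}, "p": {"s1": 72}},
            taxonomy={"f": dict(rank="species", species="Crangon crangon"),
                      "p": dict(rank="species", species="Corophium volutator")},
            samples={"s1": {}},
        )
        out, rec = F.remove_focal_taxa(t, ["Crangon crangon"])
        assert list(out.motu_ids) == ["p"]
        assert rec.details["focal_proportions"]["Crangon crangon"]["s1"] == \
            pytest.approx(0.28)

    def test_missing_focal_warns_not_fails(self, small_table):
        with pytest.warns(UserWarning, match="matches no MOTU"):
            out, _ = F.remove_focal_taxa(small_table, ["Nemo nemo"])
        assert out.equals(small_table)

    def test_two_focal_taxa_additive(self):
        t = build_table(
            counts={"f1": {"s1": 30}, "f2": {"s1": 20}, "p": {"s1": 50}},
            taxonomy={
                "f1": dict(rank="species", species="Crangon crangon"),
                "f2": dict(rank="species",
                           species="Purpureocillium lilacinum"),
                "p": dict(rank="species", species="Corophium volutator"),
            },
            samples={"s1": {}},
        )
        out, rec = F.remove_focal_taxa(
            t, ["Crangon crangon", "Purpureocillium lilacinum"]
        )
        assert list(out.motu_ids) == ["p"]
        props = rec.details["focal_proportions"]
        assert props["Crangon crangon"]["s1"] == pytest.approx(0.30)
        assert props["Purpureocillium lilacinum"]["s1"] == pytest.approx(0.20)
        assert rec.reads_in - rec.reads_out == 50


class TestSampleDepthFilter:
    def _table(self, depths: dict):
        return build_table(
            counts={"m": depths},
            taxonomy={"m": {}},
            samples={
                s: ({"sample_type": "sediment"} if s.startswith("sed") else {})
                for s in depths
            },
        )

    def test_999_dropped_1000_kept(self):
        t = self._table({"a": 999, "b": 1000})
        out, rec = F.sample_depth_filter(t, 1000, scope=("stomach",))
        assert list(out.sample_ids) == ["b"]
        assert "a" in rec.removed_samples

    def test_out_of_scope_sample_kept(self):
        t = self._table({"sed_a": 999, "b": 1500})
        out, _ = F.sample_depth_filter(t, 1000, scope=("stomach",))
        assert "sed_a" in out.sample_ids

    def test_zero_threshold_identity(self, small_table):
        out, _ = F.sample_depth_filter(small_table, 0)
        assert out.equals(small_table)

    def test_nothing_survives_errors(self):
        t = self._table({"a": 10, "b": 20})
        with pytest.raises(FilterError, match="no samples survive"):
            F.sample_depth_filter(t, 1000, scope=("stomach",))


class TestCascade:
    def test_survivors_match_hand_computation(self):
        table = cascade_fixture()
        out, report = F.run_cascade(table, FilterConfig())
        assert set(out.motu_ids) == {"mA1", "mTag", "mLow", "mPrey"}
        assert set(out.sample_ids) == {"st1", "sed1"}
        expect = pd.DataFrame(
            {"st1": [1300, 2000, 0, 1500], "sed1": [40, 100, 0, 700]},
            index=["mA1", "mTag", "mLow", "mPrey"],
        )
        got = out.counts.loc[expect.index, expect.columns]
        assert (got.to_numpy() == expect.to_numpy()).all()
        assert out.total_reads() == 5640

    def test_report_reconciles_stage_by_stage(self):
        out, report = F.run_cascade(cascade_fixture(), FilterConfig())
        report.validate_chain()
        totals = [
            ("merge_species_motus", 9275, 9275),
            ("renormalize_tag_switching", 9275, 9269),
            ("remove_contaminants", 9269, 9119),
            ("min_reads_filter", 9119, 9115),
            ("negative_control_filter", 9115, 9075),
            ("remove_focal_taxa", 9075, 6545),
            ("sample_depth_filter", 6545, 5640),
        ]
        by_stage = {r.stage: r for r in report.records}
        for stage, reads_in, reads_out in totals:
            assert by_stage[stage].reads_in == reads_in, stage
            assert by_stage[stage].reads_out == reads_out, stage

    def test_focal_proportions_in_report(self):
        _, report = F.run_cascade(cascade_fixture(), FilterConfig())
        rec = {r.stage: r for r in report.records}["remove_focal_taxa"]
        props = rec.details["focal_proportions"]["Crangon crangon"]
        assert props["st1"] == pytest.approx(1000 / 5800)
        assert props["st2"] == pytest.approx(1500 / 2405)

    def test_noop_thresholds_identity(self, small_table):
        t = small_table.subset(sample_types={"stomach", "sediment"})
        cfg = FilterConfig(
            min_reads_per_cell=1,
            min_sample_depth=0,
            focal_taxa=(),
            contaminant_rules=(),
            stage_order=("remove_contaminants", "min_reads_filter",
                         "remove_focal_taxa", "sample_depth_filter"),
        )
        out, _ = F.run_cascade(t, cfg)
        assert out.equals(t)

    def test_contaminant_and_focal_stages_commute(self):
        table = cascade_fixture()
        cfg_a = FilterConfig(stage_order=("remove_contaminants",
                                          "remove_focal_taxa"))
        cfg_b = FilterConfig(stage_order=("remove_focal_taxa",
                                          "remove_contaminants"))
        out_a, _ = F.run_cascade(table, cfg_a)
        out_b, _ = F.run_cascade(table, cfg_b)
        assert out_a.equals(out_b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            FilterConfig(tag_switch_threshold=1.5)
        with pytest.raises(ValidationError):
            FilterConfig(stage_order=("not_a_stage",))


IDEMPOTENT_STAGES = [
    lambda t: F.renormalize_tag_switching(t, 0.01),
    lambda t: F.remove_contaminants(t, F.DEFAULT_CONTAMINANT_RULES),
    lambda t: F.min_reads_filter(t, 5),
    lambda t: F.negative_control_filter(t, 0.10),
    lambda t: F.sample_depth_filter(t, 1000),
]


@pytest.mark.parametrize("stage", IDEMPOTENT_STAGES,
                         ids=["renormalize", "contaminants", "min_reads",
                              "negctrl", "depth"])
def test_threshold_stages_idempotent(stage):
    table = cascade_fixture()
    once, _ = stage(table)
    twice, _ = stage(once)
    assert twice.equals(once)


def test_focal_removal_idempotent_quiet_second_pass():
    table = cascade_fixture()
    once, _ = F.remove_focal_taxa(table, ("Crangon crangon",))
    with pytest.warns(UserWarning):
        twice, _ = F.remove_focal_taxa(once, ("Crangon crangon",))
    assert twice.equals(once)


@settings(max_examples=50, deadline=None)
@given(
    counts=arrays(np.int64, (4, 3), elements=st.integers(0, 2000)),
    stage_idx=st.integers(0, len(IDEMPOTENT_STAGES) - 1),
)
def test_stage_monotone_and_reconciled(counts, stage_idx):
    """No stage increases any cell, and its ledger reconciles exactly."""
    t = build_table(
        counts={f"m{i}": {f"s{j}": int(counts[i, j]) for j in range(3)}
                for i in range(4)},
        taxonomy={f"m{i}": {} for i in range(4)},
        samples={"s0": {}, "s1": {},
                 "s2": dict(sample_type="negative_control", site=pd.NA,
                            estuary=pd.NA)},
    )
    stage = IDEMPOTENT_STAGES[stage_idx]
    try:
        out, rec = stage(t)
    except FilterError:
        return  # nothing survives: legitimate signalled outcome
    assert rec.reads_out <= rec.reads_in
    assert rec.reconciles()
    common_m = out.counts.index.intersection(t.counts.index)
    common_s = out.counts.columns.intersection(t.counts.columns)
    assert (out.counts.loc[common_m, common_s].to_numpy()
            <= t.counts.loc[common_m, common_s].to_numpy()).all()
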