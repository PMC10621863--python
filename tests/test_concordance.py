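"""Singleton calibration, read-threshold tuning, clinical concordance, OddsPath."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdrmave.classification import (
    FUNCTIONALLY_NORMAL,
    INTERMEDIATE_FUNCTION,
    LOSS_OF_FUNCTION,
    UNSCORED,
    FunctionalCall,
)
from hdrmave.concordance import (
    BENIGN,
    NONFUNCTIONAL,
    PATHOGENIC,
    VUS,
    ClinicalLabel,
    oddspath,
    sensitivity_specificity,
    singleton_classify,
    tune_read_threshold,
)
from hdrmave.scoring import ScoreRecord


class TestSingletonClassify:
    @pytest.mark.parametrize(
        "rescue,log2,call",
        [
            (0.4, -1.32, INTERMEDIATE_FUNCTION),   # boundary enters intermediate
            (0.7, -0.51, FUNCTIONALLY_NORMAL),     # boundary enters normal
            (1.0, 0.0, FUNCTIONALLY_NORMAL),
            (0.39, -1.36, NONFUNCTIONAL),
            (0.05, -4.32, NONFUNCTIONAL),
        ],
    )
    def test_cutoffs_and_log2_display(self, rescue, log2, call):
        res = singleton_classify(rescue)
        assert res.call == call
        assert res.log2_rescue == pytest.approx(log2, abs=5e-3)

    def test_zero_rescue_nonfunctional_with_undefined_log(self):
        res = singleton_classify(0.0)
        assert res.call == NONFUNCTIONAL and math.isnan(res.log2_rescue)

    def test_negative_rescue_rejected(self):
        with pytest.raises(ValueError):
            singleton_classify(-0.1)


def _srec(label, min_in):
    return ScoreRecord(label, "missense", "siBRCA1_3UTR", (-1.0, -1.0), -1.0, 0.0, min_in)


class TestTuneReadThreshold:
    def _instance(self, counts, flags):
        records = {f"v{i}": _srec(f"v{i}", c) for i, c in enumerate(counts)}
        multi = {
            f"v{i}": LOSS_OF_FUNCTION if f else FUNCTIONALLY_NORMAL
            for i, f in enumerate(flags)
        }
        single = {f"v{i}": FUNCTIONALLY_NORMAL for i in range(len(counts))}
        return records, multi, single

    def test_toy_table(self):
        # counts {5,10,20,40}, discordant {T,T,F,F}: threshold 20 removes both
        records, multi, single = self._instance([5, 10, 20, 40], [True, True, False, False])
        rep = tune_read_threshold(records, multi, single, target_eliminated=2)
        assert rep.threshold == 20
        assert rep.n_discordant_eliminated == 2
        assert rep.removed_variants == ["v0", "v1"]

    def test_zero_target_returns_minimum(self):
        records, multi, single = self._instance([5, 10, 20], [False, False, False])
        rep = tune_read_threshold(records, multi, single, target_eliminated=0)
        assert rep.threshold == 5 and not rep.removed_variants

    def test_unreachable_target_is_error(self):
        records, multi, single = self._instance([5, 10], [True, False])
        with pytest.raises(ValueError, match="exceeds"):
            tune_read_threshold(records, multi, single, target_eliminated=2)

    def test_no_overlap_is_error(self):
        records = {"a": _srec("a", 5)}
        with pytest.raises(ValueError, match="shared"):
            tune_read_threshold(records, {"a": LOSS_OF_FUNCTION}, {"b": NONFUNCTIONAL}, 0)

    @settings(max_examples=30, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(1, 200), st.booleans()), min_size=2, max_size=60
        ),
        target_frac=st.floats(0, 1),
    )
    def test_matches_exhaustive_search(self, data, target_frac):
        """The returned threshold equals brute force over all candidates."""
        counts = [c for c, _ in data]
        flags = [f for _, f in data]
        records, multi, single = self._instance(counts, flags)
        n_disc = sum(flags)
        target = int(round(target_frac * n_disc))
        discordant = {f"v{i}" for i, f in enumerate(flags) if f}

        best = None
        for t in sorted(set(counts)):
            eliminated = sum(1 for v in discordant if records[v].min_input_count < t)
            if eliminated >= target:
                best = t
                break
        if best is None:
            with pytest.raises(ValueError):
                tune_read_threshold(records, multi, single, target)
        else:
            rep = tune_read_threshold(records, multi, single, target)
            assert rep.threshold == best


class TestSensitivitySpecificity:
    def _calls(self, spec):
        return [FunctionalCall(label, call) for label, call in spec]

    def test_perfect_concordance_is_100_100(self):
        # 5 benign all normal, 11 pathogenic all LOF
        calls = self._calls(
            [(f"b{i}", FUNCTIONALLY_NORMAL) for i in range(5)]
            + [(f"p{i}", LOSS_OF_FUNCTION) for i in range(11)]
        )
        labels = [ClinicalLabel(f"b{i}", BENIGN) for i in range(5)] + [
            ClinicalLabel(f"p{i}", PATHOGENIC) for i in range(11)
        ]
        rep = sensitivity_specificity(calls, labels)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.n_pathogenic_scored == 11 and rep.n_benign_scored == 5

    def test_intermediate_counts_as_failure(self):
        calls = self._calls(
            [(f"p{i}", LOSS_OF_FUNCTION) for i in range(4)] + [("p4", INTERMEDIATE_FUNCTION)]
        )
        labels = [ClinicalLabel(f"p{i}", PATHOGENIC) for i in range(5)]
        rep = sensitivity_specificity(calls, labels)
        assert rep.sensitivity == pytest.approx(0.8)

    def test_unscored_excluded_from_denominator(self):
        calls = self._calls([("p0", LOSS_OF_FUNCTION)]) + [
            FunctionalCall("p1", UNSCORED, frozenset({"high_variance"}))
        ]
        labels = [ClinicalLabel("p0", PATHOGENIC), ClinicalLabel("p1", PATHOGENIC)]
        rep = sensitivity_specificity(calls, labels)
        assert rep.sensitivity == 1.0 and rep.n_pathogenic_scored == 1

    def test_empty_control_set_is_undefined_not_zero(self):
        calls = self._calls([("p0", LOSS_OF_FUNCTION)])
        rep = sensitivity_specificity(calls, [ClinicalLabel("p0", PATHOGENIC)])
        assert rep.specificity is None and rep.n_benign_scored == 0

    def test_duplicate_records_do_not_move_metrics(self):
        calls = self._calls([("p0", LOSS_OF_FUNCTION), ("b0", FUNCTIONALLY_NORMAL)])
        labels = [ClinicalLabel("p0", PATHOGENIC), ClinicalLabel("b0", BENIGN)]
        base = sensitivity_specificity(calls, labels)
        dup = sensitivity_specificity(calls * 3, labels * 2)
        assert (base.sensitivity, base.specificity) == (dup.sensitivity, dup.specificity)
        assert base.confusion.equals(dup.confusion)

    def test_vus_summarized_separately(self):
        calls = self._calls(
            [("v0", FUNCTIONALLY_NORMAL), ("v1", LOSS_OF_FUNCTION),
             ("p0", LOSS_OF_FUNCTION), ("b0", FUNCTIONALLY_NORMAL)]
        )
        labels = [
            ClinicalLabel("v0", VUS), ClinicalLabel("v1", VUS),
            ClinicalLabel("p0", PATHOGENIC), ClinicalLabel("b0", BENIGN),
        ]
        rep = sensitivity_specificity(calls, labels)
        assert rep.vus_call_counts[FUNCTIONALLY_NORMAL] == 1
        assert rep.vus_call_counts[LOSS_OF_FUNCTION] == 1


class TestOddsPath:
    def test_control_panel_perfect_concordance_moderate(self):
        """11 pathogenic + 5 benign controls, perfect concordance: the
        one-hypothetical-discordant adjustment gives PS3 odds 5.0 and BS3
        odds 1/11, both landing in the moderate band."""
        ps3, bs3, s_ps3, s_bs3 = oddspath(
            n_pathogenic_controls=11, n_benign_controls=5,
            n_pathogenic_abnormal=11, n_benign_abnormal=0,
            n_pathogenic_normal=0, n_benign_normal=5,
        )
        assert ps3 == pytest.approx(5.0, abs=1e-9)
        assert bs3 == pytest.approx(1 / 11, abs=1e-9)
        assert (s_ps3, s_bs3) == ("moderate", "moderate")

    def test_uninformative_readout_odds_one(self):
        # P2 == P1: the abnormal set has the same composition as the panel
        ps3, bs3, s_ps3, s_bs3 = oddspath(10, 10, 5, 5, 5, 5)
        assert ps3 == pytest.approx(1.0)
        assert bs3 == pytest.approx(1.0)
        assert (s_ps3, s_bs3) == ("none", "none")

    def test_missing_control_class_is_error(self):
        with pytest.raises(ValueError):
            oddspath(5, 0, 5, 0, 0, 0)
        with pytest.raises(ValueError):
            oddspath(0, 5, 0, 0, 0, 5)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            oddspath(3, 3, 2, 0, 2, 3)

    @settings(max_examples=50, deadline=None)
    @given(
        pa=st.integers(1, 20), ba=st.integers(1, 20),
        pn=st.integers(1, 20), bn=st.integers(1, 20),
    )
    def test_role_swap_symmetry(self, pa, ba, pn, bn):
        """Swapping pathogenic/benign roles inverts the PS3 odds exactly
        (no adjustment fires when every confusion cell is occupied)."""
        npth, nben = pa + pn, ba + bn
        ps3, _, _, _ = oddspath(npth, nben, pa, ba, pn, bn)
        swapped, _, _, _ = oddspath(nben, npth, ba, pa, bn, pn)
        assert ps3 * swapped == pytest.approx(1.0)

    def test_strength_bands_monotone(self):
        panel = dict(n_pathogenic_controls=20, n_benign_controls=20)
        odds = []
        for ba in (10, 4, 1):
            o, _, _, _ = oddspath(
                n_pathogenic_abnormal=18, n_benign_abnormal=ba,
                n_pathogenic_normal=2, n_benign_normal=20 - ba, **panel
            )
            odds.append(o)
        assert odds == sorted(odds)
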