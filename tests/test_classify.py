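import random

import pytest

from calscreen.classify import (
    build_confusion,
    call_drug,
    calls_from_significance,
    fold_bin,
    fold_cmax,
    predictivity_metrics,
)
from calscreen.reference_data import DrugRecord
from calscreen.stats import DoseResult


def make_record(name, cmax_high=1.0, clinical_class="neuronally_active"):
    return DrugRecord(
        name=name, cas="0-0-0", source="test",
        free_cmax_low=cmax_high if cmax_high is not None else None,
        free_cmax_high=cmax_high,
        tested_concentrations=(0.1, 1.0, 10.0, 100.0),
        clinical_class=clinical_class, class_note="",
    )


def make_dose(drug, conc, p, mean, culture="2D"):
    significant = p < 0.05
    direction = "none" if not significant else ("up" if mean > 0 else "down")
    return DoseResult(
        drug=drug, concentration=conc, n_wells=8, mean_delta_pct=mean,
        sd_delta_pct=10.0, p_value=p, significant=significant,
        direction=direction, culture=culture, plate_id="p1",
    )


class TestFoldCmax:
    def test_acetaminophen_example(self, panel_by_name):
        fold = fold_cmax(30.0, panel_by_name["Acetaminophen"])
        assert round(fold) == 65

    def test_absent_cmax_propagates(self, panel_by_name):
        assert fold_cmax(3.0, panel_by_name["Kainic Acid"]) is None
        assert fold_bin(None) is None

    def test_4ap_arithmetic(self, panel_by_name):
        fold = fold_cmax(1.0, panel_by_name["4-Aminopyridine"])
        assert fold == pytest.approx(1.0 / 0.075)

    def test_binning(self):
        assert fold_bin(0.5) == "<=1x"
        assert fold_bin(7.0) == "<=10x"
        assert fold_bin(29.0) == "<=30x"
        assert fold_bin(65.0) == ">30x"

    def test_nonpositive_concentration_rejected(self, panel_by_name):
        with pytest.raises(ValueError):
            fold_cmax(0.0, panel_by_name["Aspirin"])


class TestCallDrug:
    def test_stimulant_called_at_lowest_significant_dose(self):
        record = make_record("stim", cmax_high=0.075)
        doses = [
            make_dose("stim", 0.37, 0.5, 9.0),
            make_dose("stim", 1.11, 0.001, 70.0),
            make_dose("stim", 3.33, 0.001, 86.0),
            make_dose("stim", 10.0, 0.001, 110.0),
        ]
        call = call_drug(doses, record)
        assert call.direction == "up"
        assert call.lowest_significant_concentration == pytest.approx(1.11)
        assert call.activity == "neuronally_active"
        assert call.seizure_flag
        assert call.fold_over_cmax == pytest.approx(1.11 / 0.075)

    def test_inactive_drug_called_none(self):
        record = make_record("quiet", clinical_class="negative_control")
        doses = [make_dose("quiet", c, 0.8, 5.0) for c in (3.7, 11.11, 33.33, 100.0)]
        call = call_drug(doses, record)
        assert call.direction == "none"
        assert call.activity == "non_active"
        assert not call.seizure_flag
        assert call.lowest_significant_concentration is None

    def test_suppressant_has_no_seizure_flag(self):
        record = make_record("damp", cmax_high=0.15)
        doses = [
            make_dose("damp", 0.11, 0.3, -27.0),
            make_dose("damp", 0.33, 0.2, -29.5),
            make_dose("damp", 1.0, 0.001, -59.8),
            make_dose("damp", 3.0, 0.001, -100.0),
        ]
        call = call_drug(doses, record)
        assert call.direction == "down"
        assert call.activity == "neuronally_active"
        assert not call.seizure_flag
        assert call.lowest_significant_concentration == pytest.approx(1.0)

    def test_missing_doses_rejected(self):
        record = make_record("x")
        with pytest.raises(ValueError, match="4 dose results"):
            call_drug([make_dose("x", 1.0, 0.5, 0.0)], record)


class TestBuildConfusion:
    def test_packaged_2d_calls(self, sig_calls, panel):
        calls = calls_from_significance(sig_calls, panel, "2D")
        cm = build_confusion(calls, panel)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (17, 3, 0, 5)
        assert cm.n_active_expected == 22 and cm.n_negative_expected == 3

    def test_packaged_3d_calls(self, sig_calls, panel):
        cm = build_confusion(calls_from_significance(sig_calls, panel, "3D"), panel)
        assert (cm.tp, cm.tn) == (7, 3)
        assert (cm.fp, cm.fn) == (0, 15)

    def test_all_correct_toy_panel(self):
        panel = [make_record("a"), make_record("b"),
                 make_record("n", clinical_class="negative_control")]
        doses = {
            "a": [make_dose("a", c, 0.01, 50.0) for c in (1, 2, 3, 4)],
            "b": [make_dose("b", c, 0.01, -50.0) for c in (1, 2, 3, 4)],
            "n": [make_dose("n", c, 0.9, 1.0) for c in (1, 2, 3, 4)],
        }
        calls = [call_drug(doses[r.name], r) for r in panel]
        cm = build_confusion(calls, panel)
        assert (cm.fp, cm.fn) == (0, 0)
        report = predictivity_metrics(cm)
        assert report.predictivity is not None

    def test_mismatched_calls_rejected(self, sig_calls, panel):
        calls = calls_from_significance(sig_calls, panel, "2D")
        with pytest.raises(ValueError, match="mismatch"):
            build_confusion(calls[:-1], panel)


class TestPredictivityMetrics:
    def test_2d_headline_numbers(self, sig_calls, panel):
        cm = build_confusion(calls_from_significance(sig_calls, panel, "2D"), panel)
        report = predictivity_metrics(cm)
        assert report.specificity == pytest.approx(100.0)
        assert round(report.predictivity) == 91
        assert report.ppv == pytest.approx(100.0)

    def test_3d_headline_number(self, sig_calls, panel):
        cm = build_confusion(calls_from_significance(sig_calls, panel, "3D"), panel)
        assert round(predictivity_metrics(cm).predictivity) == 45

    def test_denominator_convention_is_unique(self, sig_calls, panel):
        # among the candidate denominators, only the expected-active count
        # reproduces both published headline percentages simultaneously
        matches = []
        for label, denom_of in (
            ("panel", lambda cm: 25),
            ("active", lambda cm: cm.n_active_expected),
            ("tp_tn", lambda cm: cm.tp + cm.tn),
        ):
            values = []
            for culture in ("2D", "3D"):
                cm = build_confusion(calls_from_significance(sig_calls, panel, culture), panel)
                values.append(round(100.0 * (cm.tp + cm.tn) / denom_of(cm)))
            if values == [91, 45]:
                matches.append(label)
        assert matches == ["active"]

    def test_permutation_invariance(self, sig_calls, panel):
        calls = calls_from_significance(sig_calls, panel, "2D")
        baseline = predictivity_metrics(build_confusion(calls, panel))
        rng = random.Random(0)
        for _ in range(5):
            shuffled_calls = calls[:]
            shuffled_panel = list(panel)
            rng.shuffle(shuffled_calls)
            rng.shuffle(shuffled_panel)
            report = predictivity_metrics(build_confusion(shuffled_calls, shuffled_panel))
            assert report.confusion == baseline.confusion
            assert report.predictivity == baseline.predictivity

    def test_metrics_bit_stable_across_runs(self, sig_calls, panel):
        reports = [
            predictivity_metrics(
                build_confusion(calls_from_significance(sig_calls, panel, "2D"), panel)
            )
            for _ in range(3)
        ]
        assert len({(r.sensitivity, r.specificity, r.ppv, r.npv, r.predictivity)
                    for r in reports}) == 1

    def test_undefined_ratios_are_absent(self):
        panel = [make_record("a"), make_record("b")]  # no negatives at all
        doses = {
            name: [make_dose(name, c, 0.01, 50.0) for c in (1, 2, 3, 4)]
            for name in ("a", "b")
        }
        calls = [call_drug(doses[r.name], r) for r in panel]
        report = predictivity_metrics(build_confusion(calls, panel))
        assert report.specificity is None  # TN + FP == 0
        assert report.sensitivity == pytest.approx(100.0)
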