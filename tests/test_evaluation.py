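import numpy as np
import pytest

from spcnet.evaluation import (
    DetectionOutcome,
    combine_predictions,
    lesion_detected,
    per_lesion_eval,
    per_patient_eval,
    per_pixel_eval,
    pick_thresholds,
    radiologist_as_prediction,
)
from spcnet.labels import SoftLabelVolume
from spcnet.lesions import Lesion
from spcnet.model import ProbabilityVolume
from spcnet.training import PreparedCase
from spcnet.volume import ImageVolume, VolumeError

from oracles import mann_whitney_auc

IN_PLANE, SLICE = 1.0, 3.0


def _prob_from_labels(labels: SoftLabelVolume, noise=0.0, rng=None):
    """A predictor: ground-truth labels as probabilities (optionally noisy)."""
    probs = labels.probs.copy()
    if noise:
        probs = probs + rng.uniform(0, noise, probs.shape)
        probs /= probs.sum(axis=0, keepdims=True)
    return ProbabilityVolume(probs, IN_PLANE, SLICE)


def _case(hard, gland=None, ungraded=None, case_id="c0", tag="prostatectomy-like"):
    hard = np.asarray(hard)
    probs = np.stack([(hard == c).astype(float) for c in range(3)])
    ung = np.zeros(hard.shape, bool) if ungraded is None else ungraded
    probs[:, ung] = np.array([0.0, 0.5, 0.5])[:, None]
    labels = SoftLabelVolume(probs, ung, IN_PLANE, SLICE)
    gland = np.ones(hard.shape, bool) if gland is None else gland
    rng = np.random.default_rng(0)
    return PreparedCase(
        case_id, rng.standard_normal(hard.shape), rng.standard_normal(hard.shape),
        gland, labels, tag,
    )


def _big_case(seed=0, tag="prostatectomy-like"):
    """A gland spanning several slices with an embedded mixed lesion."""
    shape = (8, 24, 24)
    gland = np.zeros(shape, bool)
    gland[1:7, 4:20, 4:20] = True
    hard = np.zeros(shape, int)
    if tag != "normal":
        hard[2:5, 6:14, 6:14] = 1
        hard[2:5, 8:12, 8:12] = 2  # core is 25% of the lesion
    return _case(hard, gland, case_id=f"b{seed}", tag=tag)


THRESH = {"normal": 0.5, "indolent": 0.5, "aggressive": 0.5, "cancer": 0.5}


class TestPerPixel:
    def test_perfect_predictor_auc_one(self):
        case = _big_case()
        pred = _prob_from_labels(case.labels)
        rep = per_pixel_eval([case], [pred], THRESH)
        for name in ("normal", "indolent", "aggressive"):
            assert rep.entries[name]["auc"] == pytest.approx(1.0)

    def test_constant_predictor_auc_half(self):
        case = _big_case()
        probs = np.full((3,) + case.t2w.shape, 1 / 3)
        pred = ProbabilityVolume(probs, IN_PLANE, SLICE)
        rep = per_pixel_eval([case], [pred], THRESH)
        for name in ("normal", "indolent", "aggressive"):
            assert rep.entries[name]["auc"] == pytest.approx(0.5)

    def test_auc_matches_mann_whitney_oracle(self):
        """Pooled pixel AUC equals the brute-force pairwise AUC."""
        rng = np.random.default_rng(1)
        case = _big_case()
        pred = _prob_from_labels(case.labels, noise=0.8, rng=rng)
        rep = per_pixel_eval([case], [pred], THRESH)
        gland = case.gland[2:5]  # cancer-annotated slices
        hard = case.labels.hard_labels()[2:5][gland]
        for c, name in enumerate(("normal", "indolent", "aggressive")):
            s = pred.probs[c, 2:5][gland]
            expect = mann_whitney_auc((hard == c).astype(int), s)
            assert rep.entries[name]["auc"] == pytest.approx(expect, abs=1e-9)

    def test_ungraded_excluded_for_cancer_classes_only(self):
        hard = np.zeros((1, 4, 4), int)
        hard[0, 0] = 1
        ung = np.zeros(hard.shape, bool)
        ung[0, 1] = True
        case = _case(hard, ungraded=ung)
        pred = _prob_from_labels(case.labels)
        rep = per_pixel_eval([case], [pred], THRESH)
        n_all = case.gland.sum()
        assert rep.entries["normal"]["n_pixels"] == n_all
        assert rep.entries["indolent"]["n_pixels"] == n_all - 4
        assert rep.entries["aggressive"]["n_pixels"] == n_all - 4

    def test_sensitivity_specificity_identities(self):
        rng = np.random.default_rng(2)
        case = _big_case()
        pred = _prob_from_labels(case.labels, noise=0.5, rng=rng)
        rep = per_pixel_eval([case], [pred], THRESH)
        for entry in rep.entries.values():
            tp, fn, tn, fp = entry["tp"], entry["fn"], entry["tn"], entry["fp"]
            if tp + fn:
                assert entry["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert entry["specificity"] == pytest.approx(tn / (tn + fp))

    def test_absent_class_warns_and_reports_none(self):
        case = _big_case(tag="normal")
        pred = _prob_from_labels(case.labels)
        with pytest.warns(UserWarning, match="one class absent"):
            rep = per_pixel_eval([case], [pred], THRESH)
        assert rep.entries["aggressive"]["auc"] is None


class TestLesionDetected:
    def _lesion(self, voxels):
        return Lesion(1, np.asarray(voxels), 300.0, 0.5, True, True)

    def test_uniform_high_probability_detected(self):
        lesion = self._lesion([[0, 0, i] for i in range(10)])
        score = np.full((1, 1, 10), 0.8)
        assert lesion_detected(lesion, score, 0.5)

    def test_single_hot_voxel_not_detected(self):
        """Nine voxels at 0.1 and one at 0.99: the interpolated 90th
        percentile is 0.1 + 0.1*(0.99-0.1) = 0.189, below 0.5."""
        lesion = self._lesion([[0, 0, i] for i in range(10)])
        score = np.full((1, 1, 10), 0.1)
        score[0, 0, 9] = 0.99
        assert np.percentile(score[0, 0], 90) == pytest.approx(0.189)
        assert not lesion_detected(lesion, score, 0.5)

    def test_threshold_one_never_detected(self):
        lesion = self._lesion([[0, 0, i] for i in range(10)])
        score = np.ones((1, 1, 10))
        assert not lesion_detected(lesion, score, 1.0)  # strict >

    def test_ge_mode(self):
        lesion = self._lesion([[0, 0, i] for i in range(10)])
        score = np.full((1, 1, 10), 0.5)
        assert not lesion_detected(lesion, score, 0.5, strict=True)
        assert lesion_detected(lesion, score, 0.5, strict=False)


class TestPerLesion:
    def test_ground_truth_as_prediction_perfect(self):
        cases = [_big_case(0), _big_case(1, tag="normal")]
        scores = [c.labels.probs[1] + c.labels.probs[2] for c in cases]
        rep = per_lesion_eval(cases, scores, 0.5, mode="all", min_volume_mm3=250.0)
        e = rep.entries["all"]
        assert e["sensitivity"] == 1.0 and e["specificity"] == 1.0
        assert e["auc"] == pytest.approx(1.0)

    def test_auc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        cases = [_big_case(i) for i in range(2)]
        preds = [_prob_from_labels(c.labels, noise=1.5, rng=rng) for c in cases]
        scores = [p.cancer_probability() for p in preds]
        rep = per_lesion_eval(cases, scores, 0.5, mode="all", min_volume_mm3=250.0)
        # recompute the pooled scores independently
        from spcnet.evaluation import case_ground_truth_lesions, _percentile_score
        from spcnet.lesions import benign_sextants, build_sextants

        pos, neg = [], []
        for case, s in zip(cases, scores):
            for l in case_ground_truth_lesions(case):
                pos.append(_percentile_score(s[tuple(l.voxels.T)]))
            part = build_sextants(
                ImageVolume(case.gland.astype(np.uint8), IN_PLANE, SLICE, is_mask=True)
            )
            for sid in benign_sextants(part, case.labels):
                neg.append(_percentile_score(s[part.mask(sid)]))
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        expect = mann_whitney_auc(y, np.r_[pos, neg])
        assert rep.entries["all"]["auc"] == pytest.approx(expect, abs=1e-9)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        cases = [_big_case(i) for i in range(2)]
        preds = [_prob_from_labels(c.labels, noise=1.5, rng=rng) for c in cases]
        scores = [p.cancer_probability() for p in preds]
        rep1 = per_lesion_eval(cases, scores, 0.5, mode="all")
        # strictly monotone transform of the scores
        rep2 = per_lesion_eval(
            cases, [np.exp(2 * s) for s in scores], 0.5, mode="all"
        )
        assert rep1.entries["all"]["auc"] == pytest.approx(
            rep2.entries["all"]["auc"], abs=1e-12
        )

    def test_cs_mode_uses_significant_lesions_only(self):
        cases = [_big_case(0)]
        scores = [cases[0].labels.probs[2]]
        rep = per_lesion_eval(
            cases, scores, 0.5, mode="cs", significance_rule="1pct",
            min_volume_mm3=250.0,
        )
        assert rep.entries["cs_1pct"]["n_lesions"] == 1

    def test_threshold_sweep_se_down_sp_up(self):
        rng = np.random.default_rng(5)
        cases = [_big_case(i) for i in range(2)]
        preds = [_prob_from_labels(c.labels, noise=1.0, rng=rng) for c in cases]
        scores = [p.cancer_probability() for p in preds]
        ses, sps = [], []
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            e = per_lesion_eval(cases, scores, thr, mode="all").entries["all"]
            ses.append(e["sensitivity"])
            sps.append(e["specificity"])
        assert ses == sorted(ses, reverse=True)
        assert sps == sorted(sps)


class TestPerPatient:
    def test_all_zero_predictions(self):
        cases = [_big_case(0), _big_case(1, tag="normal")]
        preds = []
        for c in cases:
            probs = np.zeros((3,) + c.t2w.shape)
            probs[0] = 1.0
            preds.append(ProbabilityVolume(probs, IN_PLANE, SLICE))
        out = per_patient_eval(cases, preds, 0.5)
        assert out.sensitivity == 0.0 and out.specificity == 1.0

    def test_ground_truth_prediction_perfect(self):
        cases = [_big_case(0), _big_case(1, tag="normal")]
        preds = [_prob_from_labels(c.labels) for c in cases]
        out = per_patient_eval(cases, preds, 0.5)
        assert out.sensitivity == 1.0 and out.specificity == 1.0

    def test_one_of_two_cs_lesions_suffices(self):
        shape = (8, 24, 48)
        gland = np.zeros(shape, bool)
        gland[1:7, 4:20, 4:44] = True
        hard = np.zeros(shape, int)
        hard[2:5, 6:14, 6:14] = 2  # CS lesion 1 (detected)
        hard[2:5, 6:14, 30:38] = 2  # CS lesion 2 (missed)
        case = _case(hard, gland, case_id="two")
        probs = np.zeros((3,) + shape)
        probs[2][hard == 2] = 1.0
        probs[2][:, :, 24:] = 0.0  # miss the second lesion
        probs[0] = 1 - probs[2]
        pred = ProbabilityVolume(probs, IN_PLANE, SLICE)
        out = per_patient_eval([case], [pred], 0.5)
        assert out.true_positives == 1 and out.false_negatives == 0

    def test_undefined_ratio_is_none(self):
        out = DetectionOutcome(0, 0, 3, 1)
        assert out.sensitivity is None
        assert out.specificity == pytest.approx(0.75)


class TestRadiologistAndCombined:
    def test_empty_outline_all_normal(self):
        outline = ImageVolume(np.zeros((2, 4, 4), np.uint8), IN_PLANE, SLICE, is_mask=True)
        pred = radiologist_as_prediction(outline)
        np.testing.assert_allclose(pred.probs[0], 1.0)
        np.testing.assert_allclose(pred.probs[2], 0.0)

    def test_outline_is_aggressive_probability_one(self):
        data = np.zeros((2, 4, 4), np.uint8)
        data[0, 1:3, 1:3] = 1
        pred = radiologist_as_prediction(ImageVolume(data, IN_PLANE, SLICE, is_mask=True))
        np.testing.assert_allclose(pred.probs[2], data.astype(float))
        np.testing.assert_allclose(pred.probs.sum(axis=0), 1.0)
        np.testing.assert_allclose(pred.probs[1], 0.0)

    def test_combined_with_empty_outline_equals_model(self):
        case = _big_case()
        model = _prob_from_labels(case.labels)
        empty = radiologist_as_prediction(
            ImageVolume(np.zeros(case.t2w.shape, np.uint8), IN_PLANE, SLICE, is_mask=True)
        )
        combined = combine_predictions(model, empty)
        np.testing.assert_allclose(combined[2], model.probs[2])

    def test_inside_outline_score_at_least_one(self):
        case = _big_case()
        model = _prob_from_labels(case.labels)
        data = np.zeros(case.t2w.shape, np.uint8)
        data[3, 8:12, 8:12] = 1
        radio = radiologist_as_prediction(ImageVolume(data, IN_PLANE, SLICE, is_mask=True))
        combined = combine_predictions(model, radio)
        assert (combined[2][data.astype(bool)] >= 1.0).all()

    def test_combined_sensitivity_dominates_components(self):
        """At any threshold <= 1, adding the radiologist score can only help
        detection (the statistic is monotone in the score)."""
        rng = np.random.default_rng(6)
        cases = [_big_case(i) for i in range(3)]
        model_preds = [_prob_from_labels(c.labels, noise=2.0, rng=rng) for c in cases]
        radio_preds = []
        for c in cases:
            outline = (c.labels.hard_labels() > 0) & (rng.random(c.t2w.shape) < 0.5)
            radio_preds.append(
                radiologist_as_prediction(
                    ImageVolume(outline.astype(np.uint8), IN_PLANE, SLICE, is_mask=True)
                )
            )
        for thr in (0.2, 0.5, 0.9, 1.0):
            kw = dict(mode="cs", significance_rule="1pct", min_volume_mm3=250.0)
            se_m = per_lesion_eval(
                cases, [p.probs[2] for p in model_preds], thr, **kw
            ).entries["cs_1pct"]["sensitivity"]
            se_r = per_lesion_eval(
                cases, [p.probs[2] for p in radio_preds], thr, **kw
            ).entries["cs_1pct"]["sensitivity"]
            se_c = per_lesion_eval(
                cases,
                [
                    combine_predictions(m, r)[2]
                    for m, r in zip(model_preds, radio_preds)
                ],
                thr,
                **kw,
            ).entries["cs_1pct"]["sensitivity"]
            assert se_c >= max(se_m, se_r)


class TestPickThresholds:
    def test_separated_scores_perfect_j(self):
        hard = np.zeros((1, 10, 10), int)
        hard[0, :3] = 2
        hard[0, 3:5] = 1
        case = _case(hard)
        probs = np.zeros((3,) + hard.shape)
        for c in range(3):
            probs[c][hard == c] = 0.9
            probs[c][hard != c] = 0.1 / 2
        probs /= probs.sum(axis=0, keepdims=True)
        pred = ProbabilityVolume(probs, IN_PLANE, SLICE)
        thr = pick_thresholds([case], [pred])
        for name in ("normal", "indolent", "aggressive", "cancer"):
            assert 0 < thr[name] < 1

    def test_degenerate_pool_rejected(self):
        case = _big_case(tag="normal")
        pred = _prob_from_labels(case.labels)
        with pytest.raises(VolumeError, match="one class absent"):
            pick_thresholds([case], [pred])

    def test_permutation_invariant(self):
        rng = np.random.default_rng(7)
        cases = [_big_case(i) for i in range(2)]
        preds = [_prob_from_labels(c.labels, noise=0.7, rng=rng) for c in cases]
        t1 = pick_thresholds(cases, preds)
        t2 = pick_thresholds(cases[::-1], preds[::-1])
        for k in t1:
            assert t1[k] == pytest.approx(t2[k], abs=1e-12)
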