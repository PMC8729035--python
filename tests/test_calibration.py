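import numpy as np
import pytest

from ptmppi import calibration as cal
from ptmppi.synthetic import EnsembleSimSpec, generate_ensemble_outputs
from ptmppi.types import ALL_LABELS, ClassThresholds, NEGATIVE_LABEL


def _pred(cls, conf, sd, gold=None):
    """Hand-built EnsemblePrediction for threshold/filter tests."""
    from ptmppi.types import EnsemblePrediction

    return EnsemblePrediction(
        sample_id="x",
        member_probs=None,
        mean_probs=None,
        pred_class=cls,
        confidence=conf,
        confidence_sd=sd,
        gold_label=gold,
    )


class TestEnsembleAggregate:
    def test_single_member_identity(self):
        row = np.array([[0.1, 0.2, 0.05, 0.05, 0.1, 0.1, 0.4]])
        agg = cal.ensemble_aggregate(row)
        assert np.allclose(agg.mean_probs, row[0])
        assert agg.pred_class == ALL_LABELS[6]
        assert agg.confidence == pytest.approx(0.4)

    def test_two_member_mean_and_argmax(self):
        rows = np.array(
            [
                [0.2, 0.8, 0, 0, 0, 0, 0],
                [0.4, 0.6, 0, 0, 0, 0, 0],
            ],
            dtype=float,
        )
        agg = cal.ensemble_aggregate(rows)
        assert np.allclose(agg.mean_probs[:2], [0.3, 0.7])
        assert agg.pred_class == ALL_LABELS[1]
        assert agg.confidence == pytest.approx(0.7)

    def test_uniform_rows_tie_breaks_to_first_class(self):
        rows = np.full((3, 7), 1 / 7)
        agg = cal.ensemble_aggregate(rows)
        assert agg.pred_class == ALL_LABELS[0]
        assert agg.confidence == pytest.approx(1 / 7)

    def test_ragged_matrix_rejected(self):
        with pytest.raises(ValueError):
            cal.ensemble_aggregate(np.ones((2, 5)))


class TestConfidenceSd:
    def test_identical_members_zero_sd(self):
        rows = np.tile(np.array([0.9, 0.1, 0, 0, 0, 0, 0]), (5, 1))
        assert cal.confidence_sd(rows, 0) == 0.0

    def test_hand_value_point_one(self):
        rows = np.array([[0.6, 0.4, 0, 0, 0, 0, 0], [0.8, 0.2, 0, 0, 0, 0, 0]])
        assert cal.confidence_sd(rows, 0) == pytest.approx(0.1)

    def test_matches_brute_force_formula_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            M = rng.integers(1, 12)
            raw = rng.random((M, 7))
            probs = raw / raw.sum(axis=1, keepdims=True)
            agg = cal.ensemble_aggregate(probs)
            k = list(ALL_LABELS).index(agg.pred_class)
            col = probs[:, k]
            brute = np.sqrt(np.sum((col - col.mean()) ** 2) / M)
            assert abs(agg.confidence_sd - brute) < 1e-12
            # mean/argmax/max against direct evaluation
            assert np.max(np.abs(agg.mean_probs - probs.mean(axis=0))) < 1e-12
            assert k == int(np.argmax(probs.mean(axis=0)))
            assert abs(agg.confidence - probs.mean(axis=0).max()) < 1e-12


class TestComputeEce:
    def test_all_correct_full_confidence_zero(self):
        r = cal.compute_ece([1.0] * 10, [True] * 10)
        assert r.ece == 0.0

    def test_all_wrong_full_confidence_one(self):
        r = cal.compute_ece([1.0] * 10, [False] * 10)
        assert r.ece == 1.0

    def test_hand_built_two_bin_example(self):
        # bin (0, .5]: {0.3 correct, 0.4 wrong} -> acc .5, conf .35
        # bin (.5, 1]: {0.9, 0.8 both correct} -> acc 1, conf .85
        # ECE = .5*.15 + .5*.15 = 0.15
        r = cal.compute_ece([0.3, 0.4, 0.9, 0.8], [True, False, True, True], n_bins=2)
        assert r.ece == pytest.approx(0.15)
        assert r.bin_counts == [2, 2]

    def test_matches_brute_force_binning_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(1, 50))
            K = int(rng.integers(1, 12))
            conf = rng.random(n)
            corr = rng.random(n) < conf
            r = cal.compute_ece(conf, corr, K)
            brute = 0.0
            for k in range(K):
                lo, hi = k / K, (k + 1) / K
                idx = [
                    i
                    for i in range(n)
                    if (conf[i] > lo or (k == 0 and conf[i] >= 0)) and conf[i] <= hi
                ]
                if idx:
                    acc = np.mean([corr[i] for i in idx])
                    mc = np.mean([conf[i] for i in idx])
                    brute += len(idx) / n * abs(acc - mc)
            assert abs(r.ece - brute) < 1e-12
            assert sum(r.bin_counts) == n

    def test_population_selector(self):
        preds = [
            _pred("phosphorylation", 0.9, 0.0, gold="phosphorylation"),
            _pred(NEGATIVE_LABEL, 0.9, 0.0, gold=NEGATIVE_LABEL),
        ]
        assert cal.ece_of_predictions(preds, population="positive").n == 1
        assert cal.ece_of_predictions(preds, population="all").n == 2

    def test_missing_gold_rejected(self):
        with pytest.raises(ValueError, match="gold"):
            cal.ece_of_predictions([_pred("methylation", 0.5, 0.1)])


class TestDeriveThresholds:
    def test_constant_confidences(self):
        preds = [_pred("methylation", 0.6, 0.1) for _ in range(5)]
        th = cal.derive_thresholds(preds)
        assert th.conf_min["methylation"] == pytest.approx(0.6)

    def test_median_of_three(self):
        preds = [_pred("methylation", c, 0.0) for c in (0.2, 0.6, 0.4)]
        th = cal.derive_thresholds(preds)
        assert th.conf_min["methylation"] == pytest.approx(0.4)

    def test_matches_interpolated_percentile_oracle(self):
        rng = np.random.default_rng(2)
        confs = rng.random(31)
        sds = rng.random(31) * 0.3
        preds = [_pred("acetylation", c, s) for c, s in zip(confs, sds)]
        for q in (10, 50, 90):
            th = cal.derive_thresholds(preds, percentile=q)
            assert th.conf_min["acetylation"] == pytest.approx(
                float(np.percentile(confs, q))
            )
            assert th.sd_max["acetylation"] == pytest.approx(
                float(np.percentile(sds, q))
            )

    def test_uncovered_class_warns_and_is_omitted(self):
        preds = [_pred("methylation", 0.5, 0.1)]
        with pytest.warns(UserWarning):
            th = cal.derive_thresholds(preds, classes=["methylation", "acetylation"])
        assert "acetylation" not in th.conf_min


class TestFilterHighQuality:
    def _th(self):
        return ClassThresholds(
            conf_min={"phosphorylation": 0.6}, sd_max={"phosphorylation": 0.1}
        )

    def test_boundary_prediction_selected_inclusive(self):
        sel, rej = cal.filter_high_quality(
            [_pred("phosphorylation", 0.6, 0.1)], self._th()
        )
        assert len(sel) == 1 and not rej

    def test_below_confidence_rejected(self):
        sel, rej = cal.filter_high_quality(
            [_pred("phosphorylation", 0.59, 0.05)], self._th()
        )
        assert not sel and len(rej) == 1

    def test_negative_class_never_selected(self):
        th = ClassThresholds(conf_min={NEGATIVE_LABEL: 0.0}, sd_max={NEGATIVE_LABEL: 1.0})
        sel, _ = cal.filter_high_quality([_pred(NEGATIVE_LABEL, 0.99, 0.0)], th)
        assert not sel

    def test_tightening_conf_min_is_monotone(self):
        rng = np.random.default_rng(3)
        preds = [
            _pred("phosphorylation", rng.random(), rng.random() * 0.3)
            for _ in range(200)
        ]
        prev = None
        for conf_min in (0.1, 0.3, 0.5, 0.7, 0.9):
            th = ClassThresholds(
                conf_min={"phosphorylation": conf_min},
                sd_max={"phosphorylation": 0.2},
            )
            sel, _ = cal.filter_high_quality(preds, th)
            ids = {id(p) for p in sel}
            if prev is not None:
                assert ids <= prev
            prev = ids


def _sim_ece(spec):
    member, gold, _ = generate_ensemble_outputs(spec)
    mean = member.mean(axis=1)
    return cal.compute_ece(mean.max(axis=1), mean.argmax(axis=1) == gold).ece


class TestCalibrationBehaviour:
    def test_perfectly_calibrated_ensemble_near_zero_ece(self):
        spec = EnsembleSimSpec(n_samples=10_000, temperature=1.0, member_jitter=0.0, seed=7)
        assert _sim_ece(spec) < 0.02

    def test_ece_monotone_in_temperature_distortion(self):
        means = []
        for T in (1.0, 1.5, 2.5, 4.0):
            vals = [
                _sim_ece(
                    EnsembleSimSpec(
                        n_samples=2000, temperature=T, member_jitter=0.0, seed=s
                    )
                )
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))

    def test_ensemble_mean_beats_average_member_ece(self):
        """Averaging overconfident jittered members improves calibration."""
        ens, single = [], []
        for s in range(24):
            member, gold, _ = generate_ensemble_outputs(
                EnsembleSimSpec(
                    n_samples=2000, temperature=1.5, member_jitter=1.0, seed=s
                )
            )
            mean = member.mean(axis=1)
            ens.append(
                cal.compute_ece(mean.max(axis=1), mean.argmax(axis=1) == gold).ece
            )
            per_member = [
                cal.compute_ece(
                    member[:, i, :].max(axis=1),
                    member[:, i, :].argmax(axis=1) == gold,
                ).ece
                for i in range(member.shape[1])
            ]
            single.append(np.mean(per_member))
        assert np.mean(ens) <= np.mean(single)
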