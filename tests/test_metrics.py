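"""Concordance, horizon discrimination, calibration and survival strata."""

import numpy as np
import pytest

from _oracles import (
    brute_auprc,
    brute_auroc,
    brute_c_index,
    brute_km,
    random_observations,
)
from tdrank.events import IndexedObservation
from tdrank.metrics import (
    auprc,
    auroc,
    c_index,
    calibration_table,
    cox_baseline,
    horizon_days,
    horizon_labels,
    km_strata,
)


def obs(pid, length, td):
    return IndexedObservation(patient_id=pid, index_date=0, length_days=length, is_td=td)


class TestCIndex:
    def _all_td(self, n=10):
        return [obs(f"p{i}", 10 + 7 * i, True) for i in range(n)]

    def test_perfect_ranking(self):
        cohort = self._all_td()
        scores = [-o.length_days for o in cohort]
        assert c_index(scores, cohort, n_bootstrap=0).value == 1.0

    def test_reversed_ranking(self):
        cohort = self._all_td()
        scores = [float(o.length_days) for o in cohort]
        assert c_index(scores, cohort, n_bootstrap=0).value == 0.0

    def test_constant_scores_give_half(self):
        cohort = self._all_td()
        assert c_index(np.zeros(len(cohort)), cohort, n_bootstrap=0).value == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cohort = random_observations(rng, 30)
        scores = rng.standard_normal(30)
        got = c_index(scores, cohort, n_bootstrap=0).value
        assert got == pytest.approx(brute_c_index(scores, cohort))

    def test_all_censored_rejected(self):
        cohort = [obs("a", 10, False), obs("b", 20, False)]
        with pytest.raises(ValueError, match="comparable"):
            c_index([1.0, 2.0], cohort, n_bootstrap=0)

    def test_bootstrap_limits_bracket_estimate_and_shrink(self, rng):
        def run(n, seed):
            cohort = random_observations(rng, n)
            scores = np.array([-o.length_days + rng.normal(0, 20) for o in cohort])
            return c_index(scores, cohort, n_bootstrap=300, seed=seed)

        small = run(40, 1)
        large = run(200, 1)
        for r in (small, large):
            assert r.lo <= r.value <= r.hi
        assert (large.hi - large.lo) < (small.hi - small.lo)

    def test_equals_auroc_on_uncensored_single_horizon(self, rng):
        # every observation is TD with a length on one side of the horizon:
        # the comparable pairs are exactly the positive-negative pairs, so
        # concordance and AUROC coincide pair for pair
        h = horizon_days(4)
        cohort = [obs(f"q{i}", h - 50 + 100 * (i % 2), True) for i in range(20)]
        labels, mask = horizon_labels(cohort, 4)
        assert mask.all()
        scores = rng.standard_normal(20)
        assert c_index(scores, cohort, n_bootstrap=0).value == pytest.approx(
            auroc(labels, scores, n_bootstrap=0).value
        )

    def test_invariant_under_monotone_transform(self, rng):
        cohort = random_observations(rng, 40)
        scores = rng.standard_normal(40)
        base = c_index(scores, cohort, n_bootstrap=0).value
        warped = c_index(np.exp(3 * scores), cohort, n_bootstrap=0).value
        assert base == pytest.approx(warped)


class TestHorizonLabels:
    def test_td_within_horizon_positive(self):
        labels, mask = horizon_labels([obs("a", 50, True)], 2)
        assert labels[0] == 1 and mask[0]

    def test_censored_before_horizon_excluded(self):
        labels, mask = horizon_labels([obs("a", 40, False)], 2)
        assert not mask[0]

    def test_hand_enumerated_fixture(self):
        h = horizon_days(6)  # 183 days
        cohort = [
            obs("a", h - 1, True),   # positive
            obs("b", h, True),       # positive (boundary: length <= horizon)
            obs("c", h + 1, True),   # negative
            obs("d", h - 1, False),  # excluded
            obs("e", h, False),      # negative (followed long enough)
            obs("f", h + 50, False), # negative
            obs("g", 1, True),       # positive
            obs("h", 1, False),      # excluded
        ]
        labels, mask = horizon_labels(cohort, 6)
        assert labels.tolist() == [1, 1, 0, 0, 0, 0, 1, 0]
        assert mask.tolist() == [True, True, True, False, True, True, True, False]


class TestBinaryMetrics:
    def test_perfect_separation(self):
        labels = [0, 0, 1, 1]
        scores = [0.1, 0.2, 0.8, 0.9]
        assert auroc(labels, scores, n_bootstrap=0).value == 1.0
        assert auprc(labels, scores, n_bootstrap=0).value == 1.0

    def test_constant_scores_degenerate_values(self):
        labels = [0] * 8 + [1] * 2
        scores = [0.5] * 10
        assert auroc(labels, scores, n_bootstrap=0).value == 0.5
        assert auprc(labels, scores, n_bootstrap=0).value == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_match_threshold_sweep_oracles(self, seed):
        rng = np.random.default_rng(seed)
        labels = (rng.random(20) < 0.3).astype(int)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.standard_normal(20), 1)  # ties likely
        assert auroc(labels, scores, n_bootstrap=0).value == pytest.approx(
            brute_auroc(labels, scores)
        )
        assert auprc(labels, scores, n_bootstrap=0).value == pytest.approx(
            brute_auprc(labels, scores)
        )

    def test_single_class_names_context(self):
        with pytest.raises(ValueError, match="month"):
            auroc([1, 1], [0.1, 0.2], n_bootstrap=0, context="horizon 3 months")

    def test_monotone_transform_invariance(self, rng):
        labels = (rng.random(50) < 0.3).astype(int)
        labels[0], labels[1] = 0, 1
        scores = rng.standard_normal(50)
        for metric in (auroc, auprc):
            a = metric(labels, scores, n_bootstrap=0).value
            b = metric(labels, 2 * scores + 5, n_bootstrap=0).value
            assert a == pytest.approx(b)


class TestCalibrationTable:
    def test_equal_bins(self):
        table = calibration_table(np.linspace(0, 1, 40), np.zeros(40, dtype=int), bins=20)
        assert len(table) == 20
        assert set(table["n"]) == {2}

    def test_bin_sizes_differ_by_at_most_one(self):
        table = calibration_table(np.linspace(0, 1, 47), np.zeros(47, dtype=int), bins=20)
        assert table["n"].max() - table["n"].min() <= 1
        assert table["n"].sum() == 47

    def test_identical_scores_still_partition(self):
        table = calibration_table(np.full(40, 0.3), np.zeros(40, dtype=int), bins=20)
        assert len(table) == 20
        assert (table["mean_predicted"] == 0.3).all()

    def test_fewer_observations_than_bins_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            calibration_table([0.5] * 5, [0] * 5, bins=20)

    def test_well_calibrated_simulation(self, rng):
        scores = rng.uniform(0.01, 0.99, size=20000)
        labels = (rng.random(20000) < scores).astype(int)
        table = calibration_table(scores, labels, bins=20)
        gap = (table["mean_predicted"] - table["observed_rate"]).abs().max()
        assert gap <= 0.03


class TestKMStrata:
    def test_no_events_survival_stays_one(self):
        cohort = [obs(f"p{i}", 10 * (i + 1), False) for i in range(6)]
        curves = km_strata(np.arange(6, dtype=float), cohort, train_median=3.0)
        for curve in curves.values():
            assert (curve["survival"] == 1.0).all()

    def test_all_events_steps_by_one_over_n(self):
        cohort = [obs(f"p{i}", 10 * (i + 1), True) for i in range(5)]
        curves = km_strata(np.ones(5), cohort, train_median=0.0)  # all high stratum
        surv = curves["high"]["survival"].to_numpy()
        assert np.allclose(np.diff(surv), -0.2)

    def test_matches_hand_product_limit(self, rng):
        cohort = random_observations(rng, 12, td_fraction=0.6)
        scores = np.ones(12)
        curves = km_strata(scores, cohort, train_median=0.0)
        got = curves["high"]
        expected = dict(
            brute_km([o.length_days for o in cohort], [o.is_td for o in cohort])
        )
        for day, s in zip(got["day"], got["survival"]):
            if day in expected:
                assert s == pytest.approx(expected[day])

    def test_empty_stratum_warns_and_omits(self):
        cohort = [obs("a", 5, True), obs("b", 9, True)]
        with pytest.warns(UserWarning, match="empty"):
            curves = km_strata(np.array([1.0, 2.0]), cohort, train_median=0.0)
        assert set(curves) == {"high"}

    def test_split_invariant_under_monotone_transform(self, rng):
        cohort = random_observations(rng, 30, td_fraction=0.5)
        scores = rng.standard_normal(30)
        med = float(np.median(scores))
        a = km_strata(scores, cohort, train_median=med)
        b = km_strata(np.exp(scores), cohort, train_median=float(np.exp(med)))
        for k in a:
            assert np.allclose(a[k]["survival"], b[k]["survival"])


class TestCoxBaseline:
    def test_strong_binary_covariate_discriminates(self, rng):
        x = np.repeat([0.0, 1.0], 40)[:, None]
        lengths = np.where(x.ravel() == 1, rng.integers(5, 40, 80), rng.integers(60, 200, 80))
        cohort = [
            obs(f"p{i}", int(l), bool(rng.random() < 0.8)) for i, l in enumerate(lengths)
        ]
        scores = cox_baseline(x, cohort)
        assert scores is not None
        assert c_index(scores, cohort, n_bootstrap=0).value > 0.5

    def test_null_covariates_near_chance(self, rng):
        x = rng.standard_normal((150, 3))
        cohort = random_observations(rng, 150, td_fraction=0.5)
        scores = cox_baseline(x, cohort)
        assert scores is not None
        assert abs(c_index(scores, cohort, n_bootstrap=0).value - 0.5) < 0.12
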