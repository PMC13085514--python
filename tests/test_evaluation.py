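import numpy as np
import pytest
from scipy.stats import norm
from sklearn.linear_model import Ridge

from soildt50.evaluation import (
    Candidate,
    CVConfig,
    DegenerateBinError,
    distance_calibration,
    expected_calibration_error,
    expected_normalized_calibration_error,
    nested_cv,
)
from soildt50.features import FeatureSetSpec
from soildt50.prob_models import KernelSpec, PredictiveDistribution


def preds_from(means, stds):
    return [PredictiveDistribution(float(m), float(s)) for m, s in zip(means, stds)]


class TestECE:
    def test_perfectly_calibrated_simulation(self):
        rng = np.random.default_rng(0)
        n = 5000
        means = rng.normal(1.2, 0.8, n)
        stds = rng.uniform(0.2, 1.0, n)
        truth = rng.normal(means, stds)
        ece = expected_calibration_error(preds_from(means, stds), truth)
        assert ece < 0.03

    def test_zero_residuals_closed_form(self):
        # coverage is 1 at every level; mean(1 - p) over 0.05..0.95 = 0.5
        n = 100
        means = np.linspace(0, 1, n)
        ece = expected_calibration_error(preds_from(means, np.full(n, 0.3)), means)
        levels = np.arange(0.05, 0.951, 0.05)
        assert ece == pytest.approx(np.mean(1.0 - levels), abs=1e-12)
        assert ece == pytest.approx(0.5, abs=1e-12)

    def test_understated_sd_detected(self):
        rng = np.random.default_rng(1)
        n = 5000
        means = np.zeros(n)
        true_sd = 1.0
        truth = rng.normal(0, true_sd, n)
        stds = np.full(n, true_sd / 5.0)  # understated 5x
        ece = expected_calibration_error(preds_from(means, stds), truth)
        # analytic oracle: coverage(p) = 2 Phi(z_p / 5) - 1
        levels = np.arange(0.05, 0.951, 0.05)
        z = norm.ppf((1 + levels) / 2)
        expected = np.mean(np.abs((2 * norm.cdf(z / 5) - 1) - levels))
        assert ece > 0.2
        assert ece == pytest.approx(expected, abs=0.02)

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(2)
        means, stds = rng.normal(size=50), rng.uniform(0.1, 1, 50)
        truth = rng.normal(means, stds)
        perm = rng.permutation(50)
        a = expected_calibration_error(preds_from(means, stds), truth)
        b = expected_calibration_error(
            preds_from(means[perm], stds[perm]), truth[perm]
        )
        assert a == b

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            expected_calibration_error(preds_from([0.0], [1.0]), [0.0, 1.0])

    def test_small_n_warns(self):
        with pytest.warns(UserWarning, match="20"):
            expected_calibration_error(preds_from([0.0] * 5, [1.0] * 5), [0.0] * 5)


class TestENCE:
    def test_residuals_equal_stds(self):
        n = 40
        stds = np.linspace(0.1, 1.0, n)
        means = np.zeros(n)
        truth = stds * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        ence = expected_normalized_calibration_error(preds_from(means, stds), truth)
        assert ence == pytest.approx(0.0, abs=1e-12)

    def test_residuals_double_stds(self):
        n = 40
        stds = np.linspace(0.1, 1.0, n)
        truth = 2.0 * stds
        ence = expected_normalized_calibration_error(
            preds_from(np.zeros(n), stds), truth
        )
        assert ence == pytest.approx(1.0, abs=1e-12)

    def test_calibrated_simulation(self):
        rng = np.random.default_rng(3)
        n = 5000
        stds = rng.uniform(0.2, 1.0, n)
        truth = rng.normal(0, stds)
        ence = expected_normalized_calibration_error(
            preds_from(np.zeros(n), stds), truth, n_bins=10
        )
        assert ence < 0.1

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(4)
        stds = rng.uniform(0.1, 1, 60)
        truth = rng.normal(0, stds)
        perm = rng.permutation(60)
        a = expected_normalized_calibration_error(preds_from(np.zeros(60), stds), truth)
        b = expected_normalized_calibration_error(
            preds_from(np.zeros(60), stds[perm]), truth[perm]
        )
        assert a == pytest.approx(b, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="n_bins"):
            expected_normalized_calibration_error(
                preds_from([0.0], [1.0]), [0.0], n_bins=10
            )


class TestDistanceCalibration:
    TRAIN = ["CCO", "CCCO", "c1ccccc1", "CC(=O)O", "CCN", "c1ccncc1"]
    QUERIES = ["CCOC", "c1ccc(Cl)cc1", "CC(C)(C)C", "OCC(O)CO", "CCSCC",
               "c1ccc2ccccc2c1", "CC#N", "CCCCCCCC"]

    def test_monotone_function_gives_rho_one(self):
        from soildt50.features import tanimoto_knn_distance

        d = tanimoto_knn_distance(self.QUERIES, self.TRAIN, k=3)
        preds = preds_from(np.zeros(len(d)), 0.1 + 0.5 * d)
        r, rho = distance_calibration(preds, self.QUERIES, self.TRAIN, k=3)
        assert rho == pytest.approx(1.0)
        assert r > 0.99

    def test_independent_sd_low_correlation(self):
        rng = np.random.default_rng(5)
        queries = list(rng.choice(self.QUERIES, 200))
        preds = preds_from(np.zeros(200), rng.uniform(0.1, 1.0, 200))
        r, rho = distance_calibration(preds, queries, self.TRAIN, k=3)
        assert abs(rho) < 0.15

    def test_degenerate_flagged_nan(self):
        preds = preds_from(np.zeros(3), np.full(3, 0.5))  # constant sd
        with pytest.warns(UserWarning, match="undefined"):
            r, rho = distance_calibration(preds, ["CCO", "CCN", "CCC"], self.TRAIN, k=2)
        assert np.isnan(r) and np.isnan(rho)

    def test_too_few_queries(self):
        with pytest.raises(ValueError, match="3"):
            distance_calibration(preds_from([0, 0], [1, 1]), ["CCO", "CCN"], self.TRAIN)


@pytest.fixture(scope="module")
def cv_dataset():
    """Synthetic compounds with a linear descriptor signal for CV tests."""
    from soildt50.synthetic_data import SyntheticSpec, generate_compounds

    spec = SyntheticSpec(
        n_compounds=60, replicate_range=(3, 6), true_sigma_range=(0.2, 0.3),
        noise_sd=0.15, seed=99,
    )
    records, truth = generate_compounds(spec)
    y = truth["mu_star"].to_numpy()
    noise = np.full(len(records), 0.04)
    return records, y, noise


FAST_CANDIDATE = Candidate(
    feature_spec=FeatureSetSpec(names=("descriptors_2d",)),
    kernel_spec=KernelSpec(kind="matern25", n_restarts=1),
    label="descriptors_2d+matern25",
)


class TestNestedCV:
    def test_constant_truth_r2_nonpositive(self, cv_dataset):
        records, y, noise = cv_dataset
        rng = np.random.default_rng(0)
        pure_noise = rng.normal(0, 1, len(y))  # no structure to learn
        report = nested_cv(records, pure_noise, noise, [FAST_CANDIDATE],
                           CVConfig(outer_folds=3, inner_folds=2, seed=0))
        assert report.r2 <= 0.2  # nothing real to learn

    def test_signal_recovered_and_matches_ridge_oracle(self, cv_dataset):
        records, y, noise = cv_dataset
        cv = CVConfig(outer_folds=3, inner_folds=2, seed=1)
        report = nested_cv(records, y, noise, [FAST_CANDIDATE], cv)
        assert report.r2 > 0.3

        # independent ridge-regression oracle on the same descriptors/folds
        from sklearn.model_selection import KFold
        from soildt50.features import featurize, fit_scale, apply_scale

        raw = featurize(records, FeatureSetSpec(names=("descriptors_2d",)))
        order = np.argsort([r.compound_id for r in records], kind="stable")
        preds = np.zeros(len(y))
        for tr, te in KFold(3, shuffle=True, random_state=1).split(order):
            tr_idx, te_idx = order[tr], order[te]
            sub = fit_scale(
                type(raw)(
                    [raw.compound_ids[i] for i in tr_idx], raw.feature_names,
                    raw.values[tr_idx],
                )
            )
            model = Ridge(alpha=1.0).fit(sub.values, y[tr_idx])
            te_scaled = apply_scale(
                type(raw)(
                    [raw.compound_ids[i] for i in te_idx], raw.feature_names,
                    raw.values[te_idx],
                ),
                sub.scaler_state,
            )
            preds[te_idx] = model.predict(te_scaled.values)
        from sklearn.metrics import r2_score

        oracle_r2 = r2_score(y, preds)
        assert abs(report.r2 - oracle_r2) < 0.25

    def test_fold_assignment_deterministic(self, cv_dataset):
        records, y, noise = cv_dataset
        cv = CVConfig(outer_folds=3, inner_folds=2, seed=5)
        a = nested_cv(records, y, noise, [FAST_CANDIDATE], cv)
        perm = np.random.default_rng(0).permutation(len(records))
        b = nested_cv([records[i] for i in perm], y[perm], noise[perm],
                      [FAST_CANDIDATE], cv)
        assert a.fold_assignment == b.fold_assignment

    def test_leakage_guard(self, cv_dataset):
        """Permuting one fold's test targets leaves that fold's predictions
        bit-identical (its models never see test targets)."""
        records, y, noise = cv_dataset
        cv = CVConfig(outer_folds=3, inner_folds=2, seed=2)
        base = nested_cv(records, y, noise, [FAST_CANDIDATE], cv)
        fold0_ids = [cid for cid, f in base.fold_assignment.items() if f == 0]
        y_mod = y.copy()
        pos = [i for i, r in enumerate(records) if r.compound_id in fold0_ids]
        y_mod[pos] = np.random.default_rng(3).permutation(y_mod[pos])
        mod = nested_cv(records, y_mod, noise, [FAST_CANDIDATE], cv)
        base0 = [p for p in base.predictions if p["fold"] == 0]
        mod0 = [p for p in mod.predictions if p["fold"] == 0]
        for a, b in zip(base0, mod0):
            assert a["compound_id"] == b["compound_id"]
            assert a["pred_mean"] == b["pred_mean"]
            assert a["pred_std"] == b["pred_std"]

    def test_candidate_selection_recorded(self, cv_dataset):
        records, y, noise = cv_dataset
        cands = [
            FAST_CANDIDATE,
            Candidate(
                feature_spec=FeatureSetSpec(names=("maccs",)),
                kernel_spec=KernelSpec(kind="rbf", n_restarts=1),
                label="maccs+rbf",
            ),
        ]
        report = nested_cv(records, y, noise, cands,
                           CVConfig(outer_folds=2, inner_folds=2, seed=3))
        assert len(report.chosen_candidates) == 2
        for entry in report.chosen_candidates:
            assert entry["candidate"] in {"descriptors_2d+matern25", "maccs+rbf"}
            assert entry["inner_rmse"] is not None

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CVConfig(outer_folds=1)
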