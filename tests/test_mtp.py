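"""Linear trajectory decoder: fitting, metrics, scoring, CV, search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtpbci import mtp, paradigm, synthgen
from mtpbci.paradigm import KinematicsSeries

from conftest import MONTAGE8


def _kin_from_targets(times, Y, rate=120.0, arm="left"):
    """Kinematics whose nearest-sample match at `times` is exactly Y."""
    n = int(round(times[-1] * rate)) + 2
    v = np.zeros((n, 3))
    idx = np.round(times * rate).astype(int)
    v[idx] = Y
    return KinematicsSeries(
        times=np.arange(n) / rate,
        velocity={arm: v},
        position={arm: np.zeros((n, 3))},
        sample_rate=rate,
    )


def _lagged(X, times, n_ch=1, n_bands=1, n_lags=0):
    f = X.shape[1]
    return mtp._Lagged(
        X, times,
        np.zeros(f, dtype=int), np.zeros(f, dtype=int), np.zeros(f, dtype=int),
        ((8.0, 12.0),), [f"ch{i}" for i in range(n_ch)], 0.05, n_lags, None,
    )


class TestTrainMLR:
    def test_zero_features_intercept_only(self):
        times = np.arange(100) / 120.0
        Y = np.tile([0.3, -0.1, 0.7], (100, 1))
        kin = _kin_from_targets(times, Y)
        model = mtp.train_mlr(_lagged(np.zeros((100, 4)), times), kin, "left")
        assert np.allclose(model.intercept, [0.3, -0.1, 0.7])
        assert np.allclose(model.weights, 0.0)

    def test_recovers_generating_coefficients(self):
        """Targets built as an exact affine map of the features are
        recovered to <= 1e-6 relative error."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((400, 12))
        a_true = rng.standard_normal(3)
        B_true = rng.standard_normal((3, 12))
        times = np.arange(400) / 120.0
        kin = _kin_from_targets(times, X @ B_true.T + a_true)
        model = mtp.train_mlr(_lagged(X, times), kin, "left")
        assert np.max(np.abs(model.weights - B_true)) <= 1e-6 * np.abs(B_true).max()
        assert np.max(np.abs(model.intercept - a_true)) <= 1e-6

    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 5))
        times = np.arange(200) / 120.0
        Y = rng.standard_normal((200, 3))
        kin = _kin_from_targets(times, Y)
        model = mtp.train_mlr(_lagged(X, times), kin, "left")
        resid = Y - (X @ model.weights.T + model.intercept)
        scale = np.abs(X).max() * np.abs(Y).max() * len(X)
        assert np.max(np.abs(X.T @ resid)) <= 1e-8 * scale

    def test_beats_dense_coefficient_grid(self):
        """No (intercept, slope) pair from a dense grid achieves lower
        squared error than the least-squares fit on a tiny problem."""
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.1, 0.9, 2.3])
        a, W = mtp._ols(X, y[:, None])
        sse_ols = np.sum((y - (X[:, 0] * W[0, 0] + a[0])) ** 2)
        grid = np.linspace(-3, 3, 201)
        best = min(
            np.sum((y - (X[:, 0] * w + b)) ** 2)
            for b in grid
            for w in grid
        )
        assert sse_ols <= best + 1e-12


class TestPredict:
    def test_zero_features_predict_intercept(self):
        times = np.arange(60) / 120.0
        kin = _kin_from_targets(times, np.tile([1.0, 2.0, 3.0], (60, 1)))
        lf = _lagged(np.zeros((60, 2)), times)
        model = mtp.train_mlr(lf, kin, "left")
        pred = mtp.predict_velocity(model, lf)
        assert np.allclose(pred.velocity, [1.0, 2.0, 3.0])

    def test_output_spaced_25_ms(self):
        times = np.arange(120) / 120.0
        kin = _kin_from_targets(times, np.zeros((120, 3)))
        lf = _lagged(np.zeros((120, 2)), times)
        model = mtp.train_mlr(lf, kin, "left")
        pred = mtp.predict_velocity(model, lf, output_step=0.025)
        assert np.allclose(np.diff(pred.times), 0.025)

    def test_sigma_mismatch_raises(self):
        times = np.arange(60) / 120.0
        kin = _kin_from_targets(times, np.zeros((60, 3)))
        lf = _lagged(np.zeros((60, 2)), times)
        model = mtp.train_mlr(lf, kin, "left")
        model.sigma = np.array([[1.0, 1.0]])
        lf.sigma = np.array([[2.0, 1.0]])
        with pytest.raises(ValueError):
            mtp.predict_velocity(model, lf)


class TestSmoothing:
    def test_constant_unchanged(self):
        v = np.tile([1.0, -2.0, 0.5], (30, 1))
        assert np.allclose(mtp.smooth_prediction(v, 9), v)

    def test_impulse_spread_over_nine(self):
        v = np.zeros((31, 3))
        v[15, 0] = 1.0
        sm = mtp.smooth_prediction(v, 9)
        assert np.allclose(sm[11:20, 0], 1 / 9)
        assert np.allclose(sm[:11, 0], 0.0)

    def test_width_one_identity(self):
        v = np.random.default_rng(0).standard_normal((20, 3))
        assert np.array_equal(mtp.smooth_prediction(v, 1), v)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            mtp.smooth_prediction(np.zeros((10, 3)), 4)


class TestNormalize:
    def test_three_four_five(self):
        u, flag = mtp.normalize_velocity(np.array([3.0, 0.0, 4.0]))
        assert np.allclose(u, [0.6, 0.0, 0.8]) and not flag

    def test_zero_flagged_not_raised(self):
        u, flag = mtp.normalize_velocity(np.zeros(3))
        assert np.all(u == 0.0) and flag

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_unit_norm_or_flag(self, v):
        u, flag = mtp.normalize_velocity(np.array(v))
        if not flag:
            assert abs(np.linalg.norm(u) - 1.0) < 1e-12


class TestRelativeCoordinates:
    def test_constant_unit_velocity(self):
        v = np.tile([1.0, 0.0, 0.0], (7, 1))
        x = mtp.relative_coordinates(v)
        assert np.allclose(x, [1.0, 0.0, 0.0])

    def test_opposite_samples_cancel(self):
        v = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        x = mtp.relative_coordinates(v)
        assert np.allclose(x[1], 0.0)

    def test_single_sample(self):
        v = np.array([[0.0, 1.0, 0.0]])
        assert np.allclose(mtp.relative_coordinates(v), v)

    def test_empty_trial_raises(self):
        with pytest.raises(ValueError):
            mtp.relative_coordinates(np.empty((0, 3)))

    def test_cumsum_display_mode(self):
        v = np.tile([2.0, 0.0, 0.0], (4, 1))
        x = mtp.relative_coordinates(v, normalized=False, mode="cumsum", dt=0.5)
        assert np.allclose(x[:, 0], [1.0, 2.0, 3.0, 4.0])


class TestReconstructionError:
    def test_identical_zero(self):
        a = np.random.default_rng(0).standard_normal((10, 3))
        assert mtp.reconstruction_error(a, a) == 0.0

    def test_constant_offset(self):
        a = np.zeros((8, 3))
        b = a.copy()
        b[:, 1] += 0.7
        assert mtp.reconstruction_error(a, b) == pytest.approx(0.7)

    def test_symmetric_and_translation_invariant(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((2, 12, 3))
        shift = rng.standard_normal(3)
        e = mtp.reconstruction_error(a, b)
        assert e == mtp.reconstruction_error(b, a)
        assert mtp.reconstruction_error(a + shift, b + shift) == pytest.approx(e)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mtp.reconstruction_error(np.zeros((3, 3)), np.zeros((4, 3)))


class TestScoreChannels:
    def _model(self, weights, n_bands=2, n_ch=3, n_lags=1):
        f = n_bands * n_ch * (n_lags + 1)
        bn = np.arange(n_bands * n_ch)
        return mtp.MTPModel(
            arm="left", intercept=np.zeros(3), weights=weights,
            col_band=np.repeat(bn // n_ch, n_lags + 1),
            col_channel=np.repeat(bn % n_ch, n_lags + 1),
            col_lag=np.tile(np.arange(n_lags + 1), n_bands * n_ch),
            ch_names=[f"ch{i}" for i in range(n_ch)],
            bands=((8.0, 12.0), (12.0, 18.0))[:n_bands],
            lag_spacing=0.05, n_lags=n_lags, sigma=None, feature_step=1 / 120.0,
        )

    def test_all_zero_weights(self):
        m = self._model(np.zeros((3, 12)))
        table = mtp.score_channels([m])
        assert np.all(table.scores == 0.0)

    def test_single_coefficient_substitution(self):
        """One weight b = 2 with L = 1 gives that channel's band score
        2^2 / (L + 1) = 2."""
        w = np.zeros((3, 12))
        w[0, 0] = 2.0  # band 0, channel 0, lag 0
        table = mtp.score_channels([self._model(w)])
        assert table.scores_per_band[0, 0] == pytest.approx(2.0)
        assert table.ranking[0] == "ch0"

    def test_negation_invariance(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal((3, 12))
        a = mtp.score_channels([self._model(w)]).scores
        b = mtp.score_channels([self._model(-w)]).scores
        assert np.allclose(a, b)


class TestCrossValidation:
    def test_each_run_tested_once(self, noiseless_dataset):
        rep = mtp.crossvalidate(noiseless_dataset, 0.1, 1, arms=("left",))
        assert sorted(f.run for f in rep.folds) == [1, 2, 3, 4, 5, 6]

    def test_twelve_trials_per_fold_both_arms(self, default_dataset):
        rep = mtp.crossvalidate(default_dataset, 0.1, 1)
        for f in rep.folds:
            assert len(f.trials) == 12
            assert sum(t.direction == "forward" for t in f.trials) == 6

    def test_sigma_recomputed_per_training_split(self, default_dataset):
        rep = mtp.crossvalidate(default_dataset, 0.1, 1, arms=("left",))
        sigmas = [f.models["left"].sigma for f in rep.folds]
        assert not np.allclose(sigmas[0], sigmas[1])

    def test_run_count_guard(self, layout):
        sched = paradigm.build_offline_schedule(layout, 2, seed=0)
        rec, kin = synthgen.synthesize_mtp_session(sched, layout, seed=0)
        ds = mtp.prepare_dataset(rec, sched, kin, layout, qc=False,
                                 window_step_samples=6)
        with pytest.raises(ValueError):
            mtp.crossvalidate(ds, 0.1, 1)
        rep = mtp.crossvalidate(ds, 0.1, 1, require_six_runs=False)
        assert len(rep.folds) == 2

    def test_oracle_predictions_zero_error(self):
        """A perfect decoder's trial trajectories reproduce the target
        coordinates exactly, so eps_t vanishes."""
        v = np.tile([0.0, 1.0, 0.0], (20, 1))
        tc = mtp.relative_coordinates(v)
        assert mtp.reconstruction_error(tc, mtp.relative_coordinates(v)) == 0.0

    def test_noiseless_heldout_correlation(self, noiseless_dataset, layout):
        """On noiseless encoded data the decoder's held-out velocity
        estimates correlate with the true velocity at r > 0.99."""
        ds = noiseless_dataset
        rep = mtp.crossvalidate(ds, 0.1, 2, arms=("left",))
        vp = np.concatenate([t.pred_velocity for f in rep.folds for t in f.trials])
        idx = np.concatenate(
            [
                np.clip(np.round(t.times * 120).astype(int), 0, len(ds.kin.times) - 1)
                for f in rep.folds
                for t in f.trials
            ]
        )
        vt = ds.kin.velocity["left"][idx]
        for axis in range(3):
            assert np.corrcoef(vp[:, axis], vt[:, axis])[0, 1] > 0.99


@pytest.fixture(scope="module")
def search_results(layout):
    """Selection on a reduced montage where only C3/C4 carry signal."""
    out = {}
    for seed in (0, 1):
        sched = paradigm.build_offline_schedule(layout, 6, seed=seed)
        rec, kin = synthgen.synthesize_mtp_session(
            sched, layout, seed=seed, montage=MONTAGE8
        )
        ds = mtp.prepare_dataset(
            rec, sched, kin, layout, qc=False, window_step_samples=6
        )
        out[seed] = {
            arm: mtp.recursive_selection(
                ds, arm, lag_spacings=(0.1,), lag_counts=(1,),
                min_channels=2, max_channels=4,
            )
            for arm in ("left", "right")
        }
    return out


class TestRecursiveSelection:
    def test_encoding_channels_survive(self, search_results):
        """The contralateral encoding channel survives into the selected
        set for its arm (left arm encoded on C4, right on C3)."""
        for seed, per_arm in search_results.items():
            assert "C4" in per_arm["left"].selected_channels
            assert "C3" in per_arm["right"].selected_channels

    def test_iteration_count_and_ranking(self, search_results):
        """8 starting channels, floor 2: 7 grid evaluations, 6 drops,
        and the selected cell is the grid-wide error minimum among
        eligible sizes."""
        res = search_results[0]["left"]
        assert len(res.records) == 7
        assert len(res.elimination_order) == 6
        eligible = [r for r in res.records if 2 <= len(r.channels) <= 4]
        assert res.selected_error == min(r.best_error for r in eligible)

    def test_too_few_channels_raises(self, noiseless_dataset):
        with pytest.raises(ValueError):
            mtp.recursive_selection(
                noiseless_dataset, "left", min_channels=99
            )


def test_model_json_round_trip():
    rng = np.random.default_rng(0)
    times = np.arange(50) / 120.0
    kin = _kin_from_targets(times, rng.standard_normal((50, 3)))
    model = mtp.train_mlr(_lagged(rng.standard_normal((50, 4)), times), kin, "left")
    back = mtp.MTPModel.from_json(model.to_json())
    assert np.allclose(back.weights, model.weights)
    assert np.allclose(back.intercept, model.intercept)
    assert back.ch_names == model.ch_names
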