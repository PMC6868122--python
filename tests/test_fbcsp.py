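"""CSP, log-variance features, MI selection, RLDA, nested CV, maps."""

import numpy as np
import pytest

from mtpbci import evaluate, fbcsp as FB


def _gaussian_trials(rng, n, cov, n_samples=200):
    L = np.linalg.cholesky(cov)
    return np.einsum("cd,nds->ncs", L, rng.standard_normal((n, cov.shape[0], n_samples)))


class TestCSP:
    def test_two_channel_diagonal_example(self):
        """Class covariances diag(2,1) vs diag(1,2): filters align with
        the coordinate axes and the extreme eigenvalue is 2/3."""
        rng = np.random.default_rng(0)
        a = _gaussian_trials(rng, 60, np.diag([2.0, 1.0]))
        b = _gaussian_trials(rng, 60, np.diag([1.0, 2.0]))
        csp = FB.csp_fit(a, b, n_pairs=1)
        assert csp.eigenvalues[0] == pytest.approx(2.0 / 3.0, abs=0.02)
        w = csp.filters[0] / np.linalg.norm(csp.filters[0])
        assert max(abs(w[0]), abs(w[1])) > 0.99  # axis-aligned

    def test_identical_covariances_no_discriminability(self):
        rng = np.random.default_rng(1)
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        a = _gaussian_trials(rng, 80, cov)
        b = _gaussian_trials(rng, 80, cov)
        csp = FB.csp_fit(a, b, n_pairs=1)
        assert np.allclose(csp.eigenvalues, 0.5, atol=0.03)

    def test_matches_brute_force_variance_ratio(self):
        """The leading CSP filter attains the maximum class-a variance
        ratio found by brute force over 10^4 random unit vectors."""
        rng = np.random.default_rng(2)
        ca_true = np.array([[3.0, 0.8], [0.8, 1.0]])
        cb_true = np.array([[1.0, -0.4], [-0.4, 2.0]])
        a = _gaussian_trials(rng, 100, ca_true)
        b = _gaussian_trials(rng, 100, cb_true)
        csp = FB.csp_fit(a, b, n_pairs=1)
        ca = FB._mean_cov(a)
        cb = FB._mean_cov(b)

        def ratio(w):
            return (w @ ca @ w) / (w @ (ca + cb) @ w)

        dirs = rng.standard_normal((10_000, 2))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        brute = max(ratio(w) for w in dirs)
        assert ratio(csp.filters[0]) >= brute * 0.99

    def test_whitening_invariant(self):
        """Filters diagonalize the composite covariance to the identity."""
        rng = np.random.default_rng(3)
        a = _gaussian_trials(rng, 50, np.diag([2.0, 1.0, 0.5]))
        b = _gaussian_trials(rng, 50, np.diag([0.5, 1.0, 2.0]))
        csp = FB.csp_fit(a, b, n_pairs=1)
        comp = FB._mean_cov(a) + FB._mean_cov(b)
        W = csp.filters
        gram = W @ comp @ W.T
        assert np.allclose(gram, np.eye(len(W)), atol=1e-8)
        assert np.all((csp.eigenvalues >= 0) & (csp.eigenvalues <= 1))

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            FB.csp_fit(np.zeros((1, 2, 50)), np.zeros((5, 2, 50)), 1)


class TestLogVar:
    def test_unit_variance_near_zero(self):
        rng = np.random.default_rng(0)
        trials = rng.standard_normal((200, 1, 2048))
        f, _ = FB.logvar_features(
            trials, 120.0, 512, window=1.0, step=0.2, span=(-4.0, 12.0)
        )
        assert abs(f.mean()) < 0.1

    def test_scaling_shifts_by_2_log_c(self):
        rng = np.random.default_rng(1)
        trials = rng.standard_normal((4, 2, 2048))
        f1, _ = FB.logvar_features(trials, 120.0, 512)
        f2, _ = FB.logvar_features(3.0 * trials, 120.0, 512)
        assert np.allclose(f2 - f1, 2 * np.log(3.0), atol=1e-9)

    def test_76_window_positions(self):
        trials = np.zeros((2, 1, 1920)) + 1e-6
        f, offsets = FB.logvar_features(trials, 120.0, 480)
        assert f.shape[2] == 76
        assert offsets[0] == -4.0 and offsets[-1] == pytest.approx(11.0)

    def test_trial_too_short_raises(self):
        with pytest.raises(ValueError):
            FB.logvar_features(np.zeros((2, 1, 100)), 120.0, 480)


class TestMISelect:
    def test_label_copy_has_one_bit(self):
        y = np.array([0, 1] * 200)
        F = np.column_stack([y + 0.0, np.random.default_rng(0).standard_normal(400)])
        idx, mi = FB.mi_select(F, y, n_levels=2, k=1)
        assert idx[0] == 0
        assert mi[0] == pytest.approx(1.0, abs=0.01)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 200)
        F = rng.standard_normal((400, 3))
        _, mi = FB.mi_select(F, y, n_levels=4, k=3)
        assert np.all(mi <= 0.05)

    def test_k_equals_feature_count_identity_ordered(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1] * 100)
        F = np.column_stack(
            [rng.standard_normal(200), y + 0.1 * rng.standard_normal(200)]
        )
        idx, mi = FB.mi_select(F, y, n_levels=4, k=2)
        assert sorted(idx.tolist()) == [0, 1]
        assert mi[idx[0]] >= mi[idx[1]]

    def test_constant_feature_never_beats_informative(self):
        y = np.array([0, 1] * 50)
        F = np.column_stack([np.ones(100), y + 0.0])
        idx, mi = FB.mi_select(F, y, n_levels=4, k=1)
        assert idx[0] == 1 and mi[0] == pytest.approx(0.0, abs=1e-12)


class TestRLDA:
    def _separated(self, rng, n=100, d=4, gap=6.0):
        X0 = rng.standard_normal((n, d))
        X1 = rng.standard_normal((n, d)) + gap / np.sqrt(d)
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        return X, y

    def test_separated_gaussians_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X, y = self._separated(rng)
        model = FB.rlda_fit(X, y, gamma=0.1)
        pred = (model.signed_distance(X) > 0).astype(int)
        assert np.all(pred == y)
        # boundary passes through the midpoint of the class means
        mid = (X[y == 0].mean(0) + X[y == 1].mean(0)) / 2
        assert model.signed_distance(mid[None, :])[0] == pytest.approx(0.0, abs=1e-9)

    def test_gamma_one_parallel_to_mean_difference(self):
        rng = np.random.default_rng(1)
        X, y = self._separated(rng)
        model = FB.rlda_fit(X, y, gamma=1.0)
        diff = X[y == 1].mean(0) - X[y == 0].mean(0)
        cos = model.weights @ diff / (
            np.linalg.norm(model.weights) * np.linalg.norm(diff)
        )
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_label_swap_negates_distances(self):
        rng = np.random.default_rng(2)
        X, y = self._separated(rng)
        d1 = FB.rlda_fit(X, y, gamma=0.3).signed_distance(X)
        d2 = FB.rlda_fit(X, 1 - y, gamma=0.3).signed_distance(X)
        assert np.allclose(d1, -d2, atol=1e-9)

    def test_gamma_zero_singular_raises(self):
        X = np.zeros((10, 3))
        X[:5, 0] = 1.0
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        with pytest.raises(np.linalg.LinAlgError):
            FB.rlda_fit(X, y, gamma=0.0)


class TestMulticlassDecide:
    def test_argmax(self):
        assert FB.multiclass_decide(np.array([[2.0, -1.0, -3.0]]))[0] == 0

    def test_tie_lowest_index(self):
        assert FB.multiclass_decide(np.array([[1.0, 1.0, 1.0]]))[0] == 0

    def test_shift_invariance(self):
        d = np.array([[0.2, -0.5, 1.7], [1.0, 2.0, -1.0]])
        assert np.array_equal(
            FB.multiclass_decide(d), FB.multiclass_decide(d + 10.0)
        )


class TestPlansAndCounts:
    def test_fold_structure(self):
        assert (FB.NestedCVPlan.single_session().n_outer,
                FB.NestedCVPlan.single_session().n_inner) == (6, 5)
        assert (FB.NestedCVPlan.multi_session().n_outer,
                FB.NestedCVPlan.multi_session().n_inner) == (7, 6)

    def test_training_feature_count_worked_example(self):
        assert FB.training_feature_count(7, 5, 1) == 35


class TestNestedCVFixture:
    def test_outer_da_peak_above_85(self, fbcsp_fixture_results):
        """Contralateral mu suppression at a 2x variance ratio is
        classified with > 85% peak accuracy."""
        for _, res in fbcsp_fixture_results:
            assert res.peak > 85.0

    def test_peak_above_chance_by_rank_test(self, fbcsp_fixture_results):
        """Outer-fold peak DA exceeds the 50% chance level (paired
        Wilcoxon over the pooled outer folds, p < 0.01)."""
        peaks = np.concatenate(
            [res.fold_da.max(axis=1) for _, res in fbcsp_fixture_results]
        )
        p = evaluate.rank_test(peaks, np.full(len(peaks), 50.0), paired=True)
        assert p < 0.01

    def test_pretask_near_chance(self, fbcsp_fixture_results):
        for _, res in fbcsp_fixture_results:
            pre = res.mean_da[res.offsets <= -2.0]
            assert abs(pre.mean() - 50.0) < 15.0

    def test_contribution_maps_localize_mu_c3_c4(self, fbcsp_fixture_results):
        """The mu band dominates the MI heat map and C3/C4 carry the
        largest topography weights."""
        mu = FB.FBCSP_BANDS.index((8.0, 12.0))
        for ds, res in fbcsp_fixture_results:
            heat, topo = FB.contribution_maps(res, ds)
            assert np.argmax(heat.mean(axis=1)) == mu
            top5 = np.argsort(-topo[mu])[:5]
            names = [ds.ch_names[i] for i in top5]
            assert "C3" in names and "C4" in names

    def test_outer_fold_isolation(self, fbcsp_fixture_results):
        """Outer folds partition the runs: each trial's group appears in
        exactly one outer test fold."""
        ds, _ = fbcsp_fixture_results[0]
        folds = FB._fold_of(ds.groups, 6)
        for g in np.unique(ds.groups):
            assert len(np.unique(folds[ds.groups == g])) == 1
        assert len(np.unique(folds)) == 6

    def test_contribution_maps_flat_when_mi_zero(self, fbcsp_fixture_results):
        ds, res = fbcsp_fixture_results[0]
        import copy

        res0 = copy.deepcopy(res)
        for fm in res0.fold_models:
            for c in fm.mi_weights:
                fm.mi_weights[c][:] = 0.0
        heat, topo = FB.contribution_maps(res0, ds)
        assert np.all(heat == 0.0)
        assert all(np.all(v == 0.0) for v in topo.values())
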