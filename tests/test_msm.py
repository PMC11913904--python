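import numpy as np
import pytest
from scipy import linalg as sla

import tunnelstates as ts
from tunnelstates.msm import StateModelConfig


def simulate_chain(transition, n, seed, start=0):
    rng = np.random.default_rng(seed)
    cum = np.cumsum(transition, axis=1)
    states = np.empty(n, dtype=int)
    s = start
    for k in range(n):
        states[k] = s
        s = int(np.searchsorted(cum[s], rng.random(), side="right"))
        s = min(s, len(transition) - 1)
    return states


class TestFeaturize:
    class FakeEnsemble:
        def __init__(self, angles):
            self._angles = angles
            self.gate_residues = [1, 2]

        def angle_features(self):
            return self._angles

    def test_cos_sin_embedding(self):
        # columns are cos of both channels, then sin of both channels
        ens = self.FakeEnsemble([np.array([[0.0, np.pi / 2],
                                           [1.0, -1.0]])])
        f = ts.featurize_torsions(ens)[0]
        np.testing.assert_allclose(f[0], [1.0, 0.0, 0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(
            f[1], [np.cos(1), np.cos(1), np.sin(1), -np.sin(1)], atol=1e-12)

    def test_periodicity(self):
        theta = np.array([[0.3, -1.2], [2.0, 0.7]])
        f1 = ts.featurize_torsions(self.FakeEnsemble([theta]))[0]
        f2 = ts.featurize_torsions(
            self.FakeEnsemble([theta + 2 * np.pi]))[0]
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_zero_variance_channel_dropped(self):
        rng = np.random.default_rng(0)
        a = np.column_stack([np.zeros(50), rng.uniform(-2, 2, 50)])
        with pytest.warns(UserWarning, match="zero-variance"):
            f = ts.featurize_torsions(self.FakeEnsemble([a]))[0]
        # cos(0)=1 and sin(0)=0 are both constant: 2 of 4 columns dropped
        assert f.shape[1] == 2


class TestTICA:
    def _slow_plus_noise(self, n=20_000, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n)
        slow = np.cos(2 * np.pi * t / 5000) + 0.05 * rng.normal(size=n)
        noise = rng.normal(size=n)
        return np.column_stack([slow, noise])

    def test_first_component_loads_on_slow_channel(self):
        x = self._slow_plus_noise()
        model = ts.fit_tica([x], lag=100)
        v = model.components[:, 0]
        assert abs(v[0]) / np.linalg.norm(v) > 0.95

    def test_matches_direct_generalized_eigensolve(self):
        x = self._slow_plus_noise(seed=1)
        model = ts.fit_tica([x], lag=50)
        ridge = 1e-6 * np.trace(model.c0) / model.c0.shape[0]
        vals = sla.eigh(model.ctau,
                        model.c0 + ridge * np.eye(2), eigvals_only=True)
        np.testing.assert_allclose(sorted(model.eigenvalues),
                                   sorted(vals), atol=1e-8)

    def test_orthonormal_under_c0_metric(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5000, 4)) @ rng.uniform(0.5, 2.0, (4, 4))
        model = ts.fit_tica([x], lag=10)
        ridge = 1e-6 * np.trace(model.c0) / 4
        gram = model.components.T @ (model.c0 + ridge * np.eye(4)) \
            @ model.components
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_orthogonal_rotation_leaves_eigenvalues(self):
        x = self._slow_plus_noise(seed=3)
        q, _ = np.linalg.qr(np.random.default_rng(4).normal(size=(2, 2)))
        m1 = ts.fit_tica([x], lag=50)
        m2 = ts.fit_tica([x @ q.T], lag=50)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            ts.fit_tica([np.zeros((100, 2))], lag=50)


class TestKMeans:
    def test_separable_blobs(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(100, 2)) * 0.1 + [5, 0]
        b = rng.normal(size=(100, 2)) * 0.1 + [-5, 0]
        labels = ts.kmeans_discretize([np.vstack([a, b])], k=2, seed=1)[0]
        assert len(set(labels[:100])) == 1
        assert len(set(labels[100:])) == 1
        assert labels[0] != labels[150]

    def test_k_equals_n_frames(self):
        pts = np.arange(8, dtype=float).reshape(-1, 1) * 10
        labels = ts.kmeans_discretize([pts], k=8, seed=0)[0]
        assert len(set(labels.tolist())) == 8

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(500, 3))
        l1 = ts.kmeans_discretize([x], k=20, seed=42)[0]
        l2 = ts.kmeans_discretize([x], k=20, seed=42)[0]
        assert np.array_equal(l1, l2)


class TestEstimateMSM:
    def test_deterministic_alternation(self):
        labels = np.tile([0, 1], 500)
        model = ts.estimate_msm([labels], lag=1)
        np.testing.assert_allclose(model.transition_matrix,
                                   [[0, 1], [1, 0]], atol=1e-12)

    def test_self_transition_recovered_within_two_percent(self):
        t_true = np.array([[0.9, 0.1], [0.1, 0.9]])
        labels = simulate_chain(t_true, 50_000, seed=21)
        model = ts.estimate_msm([labels], lag=1)
        np.testing.assert_allclose(model.transition_matrix, t_true, atol=0.02)

    def test_row_stochastic_and_stationary(self):
        labels = simulate_chain(np.array([[0.8, 0.2], [0.4, 0.6]]),
                                20_000, seed=3)
        model = ts.estimate_msm([labels], lag=2)
        np.testing.assert_allclose(model.transition_matrix.sum(axis=1),
                                   1.0, atol=1e-10)
        np.testing.assert_allclose(model.stationary @ model.transition_matrix,
                                   model.stationary, atol=1e-8)

    def test_reversible_estimator_detailed_balance(self):
        labels = simulate_chain(np.array([[0.8, 0.2], [0.4, 0.6]]),
                                20_000, seed=4)
        model = ts.estimate_msm([labels], lag=1, reversible=True)
        pi = model.stationary
        t = model.transition_matrix
        np.testing.assert_allclose(pi[:, None] * t, (pi[:, None] * t).T,
                                   atol=1e-8)

    def test_stationary_matches_long_run_occupancy(self):
        t_true = np.array([[0.95, 0.05], [0.02, 0.98]])
        labels = simulate_chain(t_true, 100_000, seed=7)
        model = ts.estimate_msm([labels], lag=1)
        occupancy = np.bincount(labels) / len(labels)
        np.testing.assert_allclose(model.stationary, occupancy, atol=0.02)

    def test_disconnected_states_discarded_with_warning(self):
        labels = np.concatenate([np.tile([0, 1], 50), [2]])
        with pytest.warns(UserWarning, match="discarding"):
            model = ts.estimate_msm([labels], lag=1)
        assert list(model.active_set) == [0, 1]


class TestImpliedTimescales:
    def test_closed_form_single_lag(self):
        # lambda2 = 0.9 at lag 1 gives t2 = -1/ln 0.9 ~= 9.491
        labels = simulate_chain(np.array([[0.95, 0.05], [0.05, 0.95]]),
                                60_000, seed=8)
        table = ts.implied_timescales([labels], lags=[1])
        lam = table.iloc[0]["eigenvalue"]
        ts2 = table.iloc[0]["timescale"]
        assert ts2 == pytest.approx(-1 / np.log(lam), rel=1e-12)
        assert -1 / np.log(0.9) == pytest.approx(9.4912, abs=1e-3)

    def test_plateau_matches_generating_chain(self):
        # symmetric 2-state chain with relaxation time 200 frames
        eps = (1 - np.exp(-1 / 200)) / 2
        t_true = np.array([[1 - eps, eps], [eps, 1 - eps]])
        labels = [simulate_chain(t_true, 100_000, seed=s) for s in (30, 31)]
        table = ts.implied_timescales(labels, lags=[50, 100, 200, 400])
        t2 = table[table["index"] == 2]["timescale"].to_numpy()
        np.testing.assert_allclose(t2, 200.0, rtol=0.10)

    def test_disconnected_eigenvalue_flagged(self):
        labels = np.concatenate([np.zeros(100, int), np.ones(100, int)])
        with pytest.warns(UserWarning):
            table = ts.implied_timescales([labels[:100], labels[100:]],
                                          lags=[1])
        assert len(table) == 0 or np.isnan(table["timescale"]).all()


def block_chain(coupling, n_blocks=3, block=4):
    """Block-uniform transition matrix with weak inter-block coupling."""
    n = n_blocks * block
    t = np.full((n, n), 0.0)
    for b in range(n_blocks):
        sl = slice(b * block, (b + 1) * block)
        t[sl, sl] = 1.0 / block
    t = (1 - coupling) * t + coupling / n
    return t / t.sum(axis=1, keepdims=True)


class TestPCCA:
    def _msm_from_matrix(self, t):
        n = len(t)
        labels = simulate_chain(t, 60_000, seed=13)
        return ts.estimate_msm([labels], lag=1)

    def test_block_diagonal_recovers_blocks(self):
        t = block_chain(0.0)
        model = ts.MarkovModel(
            count_matrix=t, transition_matrix=t,
            active_set=np.arange(len(t)),
            stationary=np.full(len(t), 1 / len(t)),
            eigenvalues=np.sort(np.linalg.eigvals(t))[::-1],
            lag=1, reversible=False)
        decomp = ts.pcca(model, 3)
        crisp = decomp.crisp_map
        for b in range(3):
            assert len(set(crisp[b * 4:(b + 1) * 4].tolist())) == 1
        assert len(set(crisp.tolist())) == 3
        # memberships are crisp 0/1 for uncoupled blocks
        assert np.allclose(np.sort(decomp.memberships, axis=1)[:, -1], 1.0,
                           atol=1e-8)

    def test_weakly_coupled_blocks_fully_recovered(self):
        t = block_chain(1e-3)
        model = ts.MarkovModel(
            count_matrix=t, transition_matrix=t,
            active_set=np.arange(len(t)),
            stationary=np.full(len(t), 1 / len(t)),
            eigenvalues=np.sort(np.real(np.linalg.eigvals(t)))[::-1],
            lag=1, reversible=False)
        crisp = ts.pcca(model, 3).crisp_map
        for b in range(3):
            assert len(set(crisp[b * 4:(b + 1) * 4].tolist())) == 1
        assert len(set(crisp.tolist())) == 3

    def test_identity_when_macrostates_equal_microstates(self):
        t = np.array([[0.90, 0.05, 0.05],
                      [0.05, 0.90, 0.05],
                      [0.05, 0.05, 0.90]])
        model = ts.MarkovModel(
            count_matrix=t, transition_matrix=t, active_set=np.arange(3),
            stationary=np.full(3, 1 / 3),
            eigenvalues=np.sort(np.linalg.eigvals(t))[::-1],
            lag=1, reversible=True)
        decomp = ts.pcca(model, 3)
        assert sorted(decomp.crisp_map.tolist()) == [0, 1, 2]


class TestStateTrajectories:
    def test_single_macrostate_constant_labels(self):
        decomp = ts.MacrostateDecomposition(
            memberships=np.ones((3, 2)) * 0.5,
            crisp_map=np.zeros(3, dtype=int),
            active_set=np.arange(3), n_macrostates=2)
        macro = ts.build_state_trajectories([np.array([0, 1, 2, 1])], decomp)
        assert np.array_equal(macro[0], np.zeros(4, dtype=int))

    def test_partition_of_frames(self):
        crisp = np.array([0, 0, 1, 2])
        decomp = ts.MacrostateDecomposition(
            memberships=np.eye(4)[:, :3], crisp_map=crisp,
            active_set=np.arange(4), n_macrostates=3)
        labels = [np.array([0, 1, 2, 3, 2, 0])]
        macro = ts.build_state_trajectories(labels, decomp)
        counts = np.bincount(macro[0])
        assert counts.sum() == 6

    def test_inactive_microstates_forward_filled(self):
        crisp = np.array([0, -1, 1])
        decomp = ts.MacrostateDecomposition(
            memberships=np.eye(3)[:, :2], crisp_map=crisp,
            active_set=np.array([0, 2]), n_macrostates=2)
        macro = ts.build_state_trajectories([np.array([1, 0, 1, 2, 1])],
                                            decomp)
        assert np.array_equal(macro[0], [0, 0, 0, 1, 1])


class TestSampleStateFrames:
    def test_every_fiftieth_frame(self):
        labels = [np.zeros(250, dtype=int)]
        samples = ts.sample_state_frames(labels, stride=50)
        assert len(samples.frames[0]) == 5

    def test_provenance_fractions(self):
        labels = [np.zeros(70, dtype=int), np.zeros(30, dtype=int)]
        samples = ts.sample_state_frames(labels, stride=1,
                                         provenance=["a", "b"])
        assert samples.fractions[0]["a"] == pytest.approx(0.7, abs=0.01)
        assert samples.fractions[0]["b"] == pytest.approx(0.3, abs=0.01)

    def test_stride_one_keeps_all(self):
        labels = [np.array([0, 1, 0, 1])]
        samples = ts.sample_state_frames(labels, stride=1)
        assert len(samples.frames[0]) == 2
        assert len(samples.frames[1]) == 2


class TestConfig:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            StateModelConfig(tica_lag=0)
        with pytest.raises(ValueError):
            StateModelConfig(n_microstates=2, n_macrostates=3)
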