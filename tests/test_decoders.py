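import numpy as np
import pytest
from scipy.linalg import solve_discrete_are

from ddsbci import decoders as dec
from conftest import StubDataset

DT = 0.05


def _kinematic_A(damp_x=0.9, damp_y=0.85, coupling=0.0):
    A = np.eye(5)
    A[0, 2] = A[1, 3] = DT
    A[2, 2], A[3, 3] = damp_x, damp_y
    A[2, 3], A[3, 2] = coupling, -coupling
    return A


def _simulate_states(A, n_trials=8, n_bins=40, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        x = np.array([*rng.uniform(-0.5, 0.5, 2), *rng.uniform(-1, 1, 2), 1.0])
        states = [x]
        for _ in range(n_bins - 1):
            x = A @ x
            if noise:
                x = x + np.array([0, 0, *rng.normal(0, noise, 2), 0])
            states.append(x)
        trials.append(np.array(states))
    return trials


class TestFitVKF:
    def test_noiseless_parameter_recovery(self):
        """Exact A*, H* generative data: regression recovers both to 1e-8."""
        A_true = _kinematic_A(coupling=0.05)
        rng = np.random.default_rng(1)
        H_true = rng.normal(0, 1, size=(6, 5))
        states = _simulate_states(A_true)
        ds = StubDataset([(s @ H_true.T, s) for s in states])
        model = dec.fit_vkf(ds)
        np.testing.assert_allclose(model.A, A_true, atol=1e-8)
        np.testing.assert_allclose(model.H, H_true, atol=1e-8)

    def test_constant_state_element_preserved(self, quiet_dataset):
        model = dec.fit_vkf(quiet_dataset)
        np.testing.assert_allclose(model.A[4], [0, 0, 0, 0, 1])

    def test_frozen_gain_is_riccati_fixed_point(self):
        """The frozen K equals the steady-state gain of the discrete
        algebraic Riccati equation for the fitted (A, H, Q, R)."""
        A_true = _kinematic_A()
        rng = np.random.default_rng(2)
        H_true = rng.normal(0, 1, size=(8, 5))
        states = _simulate_states(A_true, noise=0.05, seed=3)
        rates = [s @ H_true.T + rng.normal(0, 0.5, size=(len(s), 8)) for s in states]
        model = dec.fit_vkf(StubDataset(list(zip(rates, states))))
        # independent steady state via scipy's DARE on the predicted covariance
        P_minus = solve_discrete_are(model.A.T, model.H.T, model.Q, model.R)
        K_ss = P_minus @ model.H.T @ np.linalg.inv(model.H @ P_minus @ model.H.T + model.R)
        np.testing.assert_allclose(model.K, K_ss, atol=1e-7)

    def test_rank_deficiency_reported(self):
        states = [np.tile([0.1, 0.2, 0.0, 0.0, 1.0], (20, 1))]  # constant states
        ds = StubDataset([(np.random.default_rng(0).normal(size=(20, 4)), states[0])])
        with pytest.raises(np.linalg.LinAlgError, match="state transition"):
            dec.fit_vkf(ds)


class TestVKFStep:
    def _model(self, c=4, seed=0):
        rng = np.random.default_rng(seed)
        return dec.KalmanModel(
            A=rng.normal(size=(5, 5)), H=rng.normal(size=(c, 5)),
            K=rng.normal(size=(5, c)), Q=np.eye(5), R=np.eye(c), P=np.eye(5),
        )

    def test_zero_gain_is_pure_prediction(self):
        m = self._model()
        m.K = np.zeros_like(m.K)
        x = np.array([0.1, -0.2, 0.3, 0.4, 1.0])
        np.testing.assert_allclose(dec.vkf_step(m, x, np.zeros(4)), m.A @ x)

    def test_zero_innovation_is_pure_prediction(self):
        m = self._model(seed=1)
        x = np.array([0.1, -0.2, 0.3, 0.4, 1.0])
        z = m.H @ m.A @ x
        np.testing.assert_allclose(dec.vkf_step(m, x, z), m.A @ x)

    def test_matches_hand_arithmetic(self):
        m = self._model(seed=2)
        rng = np.random.default_rng(3)
        x = rng.normal(size=5)
        z = rng.normal(size=4)
        expect = m.A @ x + m.K @ (z - m.H @ (m.A @ x))
        np.testing.assert_allclose(dec.vkf_step(m, x, z), expect, atol=1e-12)

    def test_dimension_mismatch(self):
        m = self._model()
        with pytest.raises(ValueError, match="dimension"):
            dec.vkf_step(m, np.zeros(4), np.zeros(4))
        with pytest.raises(ValueError, match="dimension"):
            dec.vkf_step(m, np.zeros(5), np.zeros(5))

    def test_unfrozen_model_rejected(self):
        m = self._model()
        m.frozen = False
        with pytest.raises(RuntimeError):
            dec.vkf_step(m, np.zeros(5), np.zeros(4))


class TestFitReFIT:
    def test_position_uncertainty_zeroed(self, clean_dataset):
        model = dec.fit_refit(clean_dataset)
        np.testing.assert_allclose(model.P[:2, :], 0.0, atol=1e-12)
        np.testing.assert_allclose(model.P[:, :2], 0.0, atol=1e-12)

    def test_gain_differs_from_vkf_on_same_data(self, clean_dataset):
        k_vkf = dec.fit_vkf(clean_dataset).K
        k_refit = dec.fit_refit(clean_dataset).K
        assert not np.allclose(k_vkf, k_refit, atol=1e-6)

    def test_relabeled_velocities_point_at_targets(self, quiet_dataset):
        from ddsbci.calibration import cardinal_targets

        targets = cardinal_targets()
        for trial, states in zip(quiet_dataset.clean_trials(), quiet_dataset.refit_states()):
            tc = np.asarray(targets[trial.target_index].center)
            for (px, py, vx, vy, _one) in states:
                speed = np.hypot(vx, vy)
                if speed < 1e-12:
                    continue
                d = tc - (px, py)
                cos = (d @ (vx, vy)) / (np.linalg.norm(d) * speed)
                assert cos == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_vkf_on_intended_equals_executed(self):
        """Straight constant-velocity reaches (executed == intended): both
        filters reduce to the same noiseless regression."""
        c = 6
        rng = np.random.default_rng(4)
        H_true = rng.normal(size=(c, 5))
        trials = []
        for _ in range(8):
            v = rng.uniform(-1, 1, size=2)
            pos = np.cumsum(np.tile(v * DT, (20, 1)), axis=0)
            states = np.column_stack([pos, np.tile(v, (20, 1)), np.ones(20)])
            trials.append((states @ H_true.T, states))
        # executed velocities already equal intended ones, so the
        # intention-relabeled states are the executed states themselves
        ds = StubDataset(trials, refit_trials=[s for _, s in trials])
        m_vkf, m_refit = dec.fit_vkf(ds), dec.fit_refit(ds)
        np.testing.assert_allclose(m_vkf.A, m_refit.A, atol=1e-8)
        np.testing.assert_allclose(m_vkf.H, m_refit.H, atol=1e-8)
        # stepping along a fresh trajectory from the same process, both
        # filters emit the same velocity estimates
        v = np.array([0.3, -0.2])
        pos = np.cumsum(np.tile(v * DT, (15, 1)), axis=0)
        states = np.column_stack([pos, np.tile(v, (15, 1)), np.ones(15)])
        for x_prev, x_next in zip(states[:-1], states[1:]):
            z = H_true @ x_next
            v1 = dec.vkf_step(m_vkf, x_prev, z)[2:4]
            v2 = dec.vkf_step(m_refit, x_prev, z)[2:4]
            np.testing.assert_allclose(v1, v2, atol=1e-6)


class TestFitDRA:
    def _linear_dataset(self, n=100, c=10, seed=0, min_speed=0.05):
        rng = np.random.default_rng(seed)
        G = rng.normal(size=(c, 2))
        b = rng.uniform(5, 20, size=c)
        V = rng.uniform(-1, 1, size=(n, 2))
        V[np.hypot(V[:, 0], V[:, 1]) < min_speed] += 0.5  # keep above filter
        Z = V @ G.T + b
        states = np.column_stack([np.zeros((n, 2)), V, np.ones(n)])
        return StubDataset([(Z, states)]), G, b, V, Z

    def test_recovers_linear_map(self):
        ds, G, b, V, Z = self._linear_dataset()
        model = dec.fit_dra(ds)
        for v, z in zip(V, Z):
            np.testing.assert_allclose(dec.dra_step(model, z), v, atol=1e-6)

    def test_all_slow_bins_rejected(self):
        n, c = 20, 4
        states = np.column_stack(
            [np.zeros((n, 2)), np.full((n, 2), 0.01), np.ones(n)]
        )
        ds = StubDataset([(np.random.default_rng(0).normal(size=(n, c)), states)])
        with pytest.raises(ValueError, match="speed filter"):
            dec.fit_dra(ds)

    def test_speed_filter_keeps_expected_bins(self):
        """20-bin trial with 8 sub-threshold bins: the fit equals an
        independent least squares on exactly the 12 surviving bins."""
        rng = np.random.default_rng(5)
        c = 6
        V = np.zeros((20, 2))
        V[:12] = rng.uniform(0.2, 1.0, size=(12, 2))  # speeds well above 0.03
        V[12:] = rng.uniform(-0.01, 0.01, size=(8, 2))  # below threshold
        Z = rng.normal(10, 2, size=(20, c))
        states = np.column_stack([np.zeros((20, 2)), V, np.ones(20)])
        model = dec.fit_dra(StubDataset([(Z, states)]))
        design = np.column_stack([Z[:12], np.ones(12)])
        B_expect, *_ = np.linalg.lstsq(design, V[:12], rcond=None)
        np.testing.assert_allclose(model.B, B_expect.T, atol=1e-8)

    def test_step_edge_cases(self):
        m = dec.LinearVelocityMap(B=np.zeros((2, 5)), n_channels=4)
        np.testing.assert_allclose(dec.dra_step(m, np.ones(4)), [0, 0])
        m2 = dec.LinearVelocityMap(
            B=np.column_stack([np.zeros((2, 4)), [0.3, -0.2]]), n_channels=4
        )
        np.testing.assert_allclose(dec.dra_step(m2, 100 * np.ones(4)), [0.3, -0.2])
        rng = np.random.default_rng(6)
        B = rng.normal(size=(2, 5))
        z = rng.normal(size=4)
        m3 = dec.LinearVelocityMap(B=B, n_channels=4)
        np.testing.assert_allclose(dec.dra_step(m3, z), B @ np.append(z, 1.0))


class TestFitWF:
    def test_tau_zero_reduces_to_dra_without_filter(self):
        rng = np.random.default_rng(7)
        n, c = 80, 5
        V = rng.uniform(0.1, 1.0, size=(n, 2))
        Z = V @ rng.normal(size=(c, 2)).T + 10
        states = np.column_stack([np.zeros((n, 2)), V, np.ones(n)])
        ds = StubDataset([(Z, states)])
        B_wf = dec.fit_wf(ds, tau=0).B
        B_dra = dec.fit_dra(ds, speed_threshold=0.0).B
        np.testing.assert_allclose(B_wf, B_dra, atol=1e-8)

    def test_recovers_lagged_dependence(self):
        """Known 2-lag generative map reproduced on held-out data to 1e-6."""
        rng = np.random.default_rng(8)
        c, tau = 4, 2
        B0, B1 = rng.normal(size=(2, c)), rng.normal(size=(2, c))
        off = np.array([0.1, -0.3])

        def make(n):
            Z = rng.normal(10, 3, size=(n, c))
            Zp = np.vstack([np.zeros((1, c)), Z[:-1]])  # zero-padded history
            V = Z @ B0.T + Zp @ B1.T + off
            return Z, np.column_stack([np.zeros((n, 2)), V, np.ones(n)])

        train = [make(60) for _ in range(3)]
        model = dec.fit_wf(StubDataset(train), tau=tau)
        Z_test, states_test = make(30)
        hist = [np.zeros(c)] * (tau + 1)
        for i in range(30):
            hist = [Z_test[i]] + hist[:-1]
            v = dec.wf_step(model, hist)
            np.testing.assert_allclose(v, states_test[i, 2:4], atol=1e-6)

    def test_zero_rates_give_offset(self):
        B = np.zeros((2, 3 * 3 + 1))
        B[:, -1] = [0.5, -0.5]
        m = dec.LinearVelocityMap(B=B, tau=2, n_channels=3, kind="wf")
        np.testing.assert_allclose(dec.wf_step(m, [np.zeros(3)] * 3), [0.5, -0.5])

    def test_current_block_only_equals_dra(self):
        rng = np.random.default_rng(9)
        c = 4
        B_cur = rng.normal(size=(2, c))
        B = np.zeros((2, c * 3 + 1))
        B[:, :c] = B_cur
        m_wf = dec.LinearVelocityMap(B=B, tau=2, n_channels=c, kind="wf")
        m_dra = dec.LinearVelocityMap(
            B=np.column_stack([B_cur, np.zeros(2)]), n_channels=c
        )
        z = rng.normal(size=c)
        hist = [z, rng.normal(size=c), rng.normal(size=c)]
        np.testing.assert_allclose(dec.wf_step(m_wf, hist), dec.dra_step(m_dra, z))

    def test_history_only_last_tau_plus_one_matters(self):
        """Frames older than tau bins never influence the command."""
        rng = np.random.default_rng(10)
        c, tau = 3, 2
        model = dec.LinearVelocityMap(
            B=rng.normal(size=(2, c * (tau + 1) + 1)), tau=tau, n_channels=c, kind="wf"
        )
        runner = dec.WFRunner(model)
        stream_a = [rng.normal(size=c) for _ in range(8)]
        stream_b = [rng.normal(size=c) for _ in range(5)] + stream_a[-3:]
        out_a = [runner.step(z, (0, 0))[0] for z in stream_a][-1]
        runner.reset((0, 0))
        out_b = [runner.step(z, (0, 0))[0] for z in stream_b][-1]
        np.testing.assert_allclose(out_a, out_b)

    def test_wrong_history_length(self):
        m = dec.LinearVelocityMap(B=np.zeros((2, 7)), tau=1, n_channels=3, kind="wf")
        with pytest.raises(ValueError):
            dec.wf_step(m, [np.zeros(3)])


def _separable_dds_dataset(seed=0, per_class=40, c=6, spread=0.05):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 5, size=(9, c))
    Z = np.vstack(
        [ctr + spread * rng.standard_normal((per_class, c)) for ctr in centers]
    )
    labels = np.repeat(np.arange(9), per_class)
    ds = StubDataset([(Z, np.zeros((len(Z), 5)))], labels=labels)
    return ds, Z, labels


class TestFitDDS:
    def test_separable_classes_high_accuracy(self):
        ds, Z, labels = _separable_dds_dataset()
        model = dec.fit_dds(ds)
        pred = [int(np.argmax(dec.softmax_probabilities(model, z))) for z in Z]
        assert np.mean(np.array(pred) == labels) >= 0.99

    def test_missing_class_reported(self):
        ds, Z, labels = _separable_dds_dataset()
        keep = labels != 4
        ds2 = StubDataset([(Z[keep], np.zeros((keep.sum(), 5)))], labels=labels[keep])
        with pytest.raises(ValueError, match=r"\[4\]"):
            dec.fit_dds(ds2)

    def test_zero_coefficients_give_uniform_probabilities(self):
        m = dec.MultinomialSelectionModel(B=np.zeros((9, 5)))
        p = dec.softmax_probabilities(m, np.random.default_rng(0).normal(size=4))
        np.testing.assert_allclose(p, np.full(9, 1 / 9))

    def test_probabilities_normalize(self):
        rng = np.random.default_rng(1)
        m = dec.MultinomialSelectionModel(B=rng.normal(size=(9, 8)))
        for _ in range(20):
            p = dec.softmax_probabilities(m, rng.normal(0, 10, size=7))
            assert p.sum() == pytest.approx(1.0)
            assert np.all(p >= 0)


class TestSelectionWeights:
    def test_saturation_at_gamma(self):
        assert dec.selection_weights(np.array([0.85]), 0.85)[0] == pytest.approx(1.0)

    def test_cutoff_at_one_minus_gamma(self):
        assert dec.selection_weights(np.array([0.15]), 0.85)[0] == pytest.approx(0.0)

    def test_midpoint(self):
        # (0.5 - 0.15) / 0.7 = 0.5
        assert dec.selection_weights(np.array([0.5]), 0.85)[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("gamma", [0.5, 0.2, 1.01, -1.0])
    def test_gamma_domain(self, gamma):
        with pytest.raises(ValueError):
            dec.selection_weights(np.array([0.5]), gamma)

    def test_monotone_in_p_and_gamma_on_grid(self):
        """w is nondecreasing in p; in gamma it tightens toward winner-take-
        all: on the linear region dw/dgamma has the sign of (1 - 2p), so w
        shrinks with gamma for confident selections (p > 1/2) and grows for
        unconfident ones (p < 1/2), pinned at 1/2 when p = 1/2."""
        p_grid = np.linspace(0, 1, 101)
        gammas = np.linspace(0.55, 1.0, 10)
        for g in gammas:
            w = dec.selection_weights(p_grid, g)
            assert np.all(np.diff(w) >= -1e-12)
        for p in p_grid:
            active = [g for g in gammas if 1 - g < p < g]
            w_seq = np.array([dec.selection_weights(np.array([p]), g)[0] for g in active])
            if p > 0.5:
                assert np.all(np.diff(w_seq) <= 1e-12)
            elif p < 0.5:
                assert np.all(np.diff(w_seq) >= -1e-12)
            else:
                np.testing.assert_allclose(w_seq, 0.5)


class TestMixSelections:
    def test_single_weight_selects_menu_entry(self):
        w = np.zeros(9)
        w[2] = 1.0
        np.testing.assert_allclose(dec.mix_selections(w), dec.MENU[2])

    def test_hand_worked_two_way_mix(self):
        p = np.zeros(9)
        p[2], p[3] = 0.6, 0.4  # fast East, slow East
        w = dec.selection_weights(p, 0.85)
        np.testing.assert_allclose(w[[2, 3]], [0.642857, 0.357143], atol=1e-6)
        xi = dec.mix_selections(w, p=p)
        np.testing.assert_allclose(xi, [0.821429, 0.0], atol=1e-6)

    def test_gamma_one_is_probability_weighted_average(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(9))
        w = dec.selection_weights(p, 1.0)
        np.testing.assert_allclose(dec.mix_selections(w, p=p), p @ dec.MENU, atol=1e-12)

    def test_all_zero_weights_fallback(self):
        p = np.full(9, 1 / 9)  # uniform < 1 - gamma: every weight zero
        w = dec.selection_weights(p, 0.85)
        assert np.all(w == 0)
        np.testing.assert_allclose(dec.mix_selections(w, p=p), dec.MENU[0])
        np.testing.assert_allclose(
            dec.mix_selections(w, p=p, fallback="stop"), [0, 0]
        )


class TestDDSStep:
    def test_dominant_logit_forces_menu_velocity(self):
        B = np.zeros((9, 4))
        B[0, -1] = 50.0  # fast North dominates
        m = dec.MultinomialSelectionModel(B=B)
        v, aux = dec.dds_step(m, np.zeros(3))
        np.testing.assert_allclose(v, [0.0, 1.0], atol=1e-10)
        assert aux["p"][0] > 0.99

    def test_uniform_probabilities_use_fallback(self):
        m = dec.MultinomialSelectionModel(B=np.zeros((9, 4)))
        v, aux = dec.dds_step(m, np.ones(3))
        assert np.all(aux["w"] == 0)
        np.testing.assert_allclose(v, dec.MENU[0])

    def test_output_in_menu_convex_hull(self):
        """DDS speed never exceeds the fastest menu selection."""
        rng = np.random.default_rng(3)
        m = dec.MultinomialSelectionModel(B=rng.normal(size=(9, 6)))
        for _ in range(10_000):
            v, _ = dec.dds_step(m, rng.normal(0, 20, size=5))
            assert np.linalg.norm(v) <= 1.0 + 1e-12

    def test_continuous_decoders_unbounded(self):
        big = dec.LinearVelocityMap(B=np.full((2, 4), 10.0), n_channels=3)
        assert np.linalg.norm(dec.dra_step(big, np.full(3, 50.0))) > 1.0


class TestFactory:
    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            dec.fit_decoder("magic", None)
        with pytest.raises(ValueError):
            dec.make_decoder("magic", None)

    @pytest.mark.parametrize("kind", ["vkf", "refit", "dra", "wf", "dds"])
    def test_one_command_per_bin(self, kind, clean_dataset):
        model = dec.fit_decoder(kind, clean_dataset)
        runner = dec.make_decoder(kind, model)
        runner.reset((0.0, 0.0))
        rng = np.random.default_rng(0)
        for _ in range(5):
            v, aux = runner.step(rng.uniform(0, 40, size=runner.n_channels), (0.0, 0.0))
            assert np.shape(v) == (2,)
            assert np.all(np.isfinite(v))
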