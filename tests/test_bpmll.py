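import numpy as np
import pytest

from sdamll import bpmll as bp
from sdamll.datamodel import MultiLabelDataset, RankedPrediction

from oracles import finite_difference, naive_instance_error


def make_ds(X, labels, N):
    X = np.asarray(X, dtype=float)
    return MultiLabelDataset(
        features=X,
        labels=labels,
        label_names=[f"L{j}" for j in range(N)],
        feature_names=[f"f{j}" for j in range(X.shape[1])],
        instance_ids=[f"g{i}" for i in range(X.shape[0])],
    )


class TestForward:
    def test_zero_params_output_half(self):
        net = bp.BpmllNetwork(V=np.zeros((4, 3)), W=np.zeros((3, 2)),
                              hidden_bias=np.zeros(3), output_bias=np.zeros(2))
        b, c = bp.forward(net, np.random.rand(4))
        assert np.allclose(b, 0.5) and np.allclose(c, 0.5)

    def test_unit_chain_values(self):
        net = bp.BpmllNetwork(V=[[1.0]], W=[[1.0]], hidden_bias=[0.0], output_bias=[0.0])
        b, c = bp.forward(net, [1.0])
        assert b[0] == pytest.approx(0.7310586, abs=1e-7)
        assert c[0] == pytest.approx(0.6750376, abs=1e-7)

    def test_outputs_in_open_unit_interval(self, rng):
        net = bp.init_network(5, 4, 3, rng)
        _, c = bp.forward(net, rng.uniform(0, 1, (20, 5)))
        assert np.all((c > 0) & (c < 1))

    def test_dimension_mismatch_rejected(self, rng):
        net = bp.init_network(5, 4, 3, rng)
        with pytest.raises(ValueError):
            bp.forward(net, np.zeros(6))


class TestInstanceError:
    def test_single_pair_value(self):
        assert bp.instance_error(np.array([0.8, 0.3]), {1}) == pytest.approx(
            0.6065307, abs=1e-7
        )

    def test_two_pair_value(self):
        # (e^{-0.8} + e^{-0.6}) / 2, evaluated directly
        assert bp.instance_error(np.array([0.9, 0.7, 0.1]), {1, 2}) == pytest.approx(
            (np.exp(-0.8) + np.exp(-0.6)) / 2, abs=1e-12
        )

    def test_equal_outputs_give_exactly_one(self, rng):
        for N in (2, 4, 7):
            c = np.full(N, float(rng.uniform(0, 1)))
            assert bp.instance_error(c, {1}) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("Y", [set(), {1, 2, 3}])
    def test_degenerate_label_sets_rejected(self, Y):
        with pytest.raises(ValueError, match="undefined"):
            bp.instance_error(np.array([0.1, 0.5, 0.9]), Y)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(100):
            N = int(rng.integers(2, 9))
            c = rng.uniform(0, 1, N)
            size = int(rng.integers(1, N))
            Y = frozenset(int(x) + 1 for x in rng.choice(N, size, replace=False))
            assert bp.instance_error(c, Y) == pytest.approx(
                naive_instance_error(c, Y), abs=1e-12
            )

    def test_raising_relevant_output_decreases_error(self, rng):
        c = rng.uniform(0.1, 0.9, 5)
        Y = {2, 4}
        base = bp.instance_error(c, Y)
        c2 = c.copy()
        c2[1] += 0.05
        assert bp.instance_error(c2, Y) < base


class TestGlobalError:
    def test_single_and_duplicated_instance(self, rng):
        net = bp.init_network(3, 2, 4, rng)
        x = rng.uniform(0, 1, 3)
        ds1 = make_ds([x], [{1, 3}], 4)
        ds2 = make_ds([x, x], [{1, 3}, {1, 3}], 4)
        e1, _ = bp.global_error(net, ds1)
        _, c = bp.forward(net, x)
        assert e1 == pytest.approx(bp.instance_error(c, {1, 3}), abs=1e-12)
        e2, _ = bp.global_error(net, ds2)
        assert e2 == pytest.approx(2 * e1, abs=1e-12)

    def test_matches_bruteforce_summation(self, rng):
        net = bp.init_network(4, 3, 5, rng)
        X = rng.uniform(0, 1, size=(30, 4))
        labels = [
            frozenset(int(x) + 1 for x in rng.choice(5, int(rng.integers(1, 5)), replace=False))
            for _ in range(30)
        ]
        ds = make_ds(X, labels, 5)
        E, skipped = bp.global_error(net, ds)
        brute = 0.0
        for i in range(30):
            _, c = bp.forward(net, X[i])
            brute += naive_instance_error(c, labels[i])
        assert skipped == 0
        assert E == pytest.approx(brute, abs=1e-12)

    def test_full_label_set_skipped_and_counted(self, rng):
        net = bp.init_network(2, 2, 3, rng)
        ds = make_ds(rng.uniform(0, 1, (2, 2)), [{1, 2, 3}, {2}], 3)
        E, skipped = bp.global_error(net, ds)
        assert skipped == 1 and np.isfinite(E)


class TestGradients:
    def test_matches_central_finite_differences(self):
        """The module's primary oracle: −update/α vs FD of E_i, both at
        random and near-symmetric (all-outputs-equal) parameter points."""
        rng = np.random.default_rng(7)
        nets = [bp.init_network(4, 3, 5, rng) for _ in range(5)]
        # near-symmetric point: tiny weights, all outputs ≈ 0.5
        nets.append(
            bp.BpmllNetwork(V=np.full((4, 3), 1e-6), W=np.full((3, 5), 1e-6),
                            hidden_bias=np.zeros(3), output_bias=np.zeros(5))
        )
        for net in nets:
            x = rng.uniform(0, 1, 4)
            Y = frozenset({1, 3})
            upd = bp.gradients(net, x, Y, alpha=1.0)

            def E():
                _, c = bp.forward(net, x)
                return bp.instance_error(c, Y)

            fd = finite_difference(E, [net.V, net.W, net.hidden_bias, net.output_bias])
            for key, g in zip(("V", "W", "hidden_bias", "output_bias"), fd):
                denom = np.maximum(np.abs(g), 1e-4)
                assert np.max(np.abs(-upd[key] - g) / denom) < 1e-5

    def test_push_relevant_up_irrelevant_down_at_symmetry(self):
        net = bp.BpmllNetwork(V=np.zeros((2, 2)), W=np.zeros((2, 2)),
                              hidden_bias=np.zeros(2), output_bias=np.zeros(2))
        upd = bp.gradients(net, np.array([0.5, 0.5]), {1}, alpha=1.0)
        d = upd["output_bias"]  # Δθ_j = α d_j
        assert d[0] > 0 and d[1] < 0

    def test_updates_linear_in_alpha(self, rng):
        net = bp.init_network(3, 2, 4, rng)
        x = rng.uniform(0, 1, 3)
        u1 = bp.gradients(net, x, {2}, alpha=0.1)
        u2 = bp.gradients(net, x, {2}, alpha=0.2)
        for k in u1:
            assert np.allclose(u2[k], 2.0 * u1[k], atol=1e-14)

    def test_step_decreases_instance_error(self, rng):
        net = bp.init_network(3, 4, 4, rng)
        x = rng.uniform(0, 1, 3)
        Y = frozenset({2})
        _, c = bp.forward(net, x)
        before = bp.instance_error(c, Y)
        upd = bp.gradients(net, x, Y, alpha=0.01)
        net.W += upd["W"]; net.V += upd["V"]
        net.output_bias += upd["output_bias"]; net.hidden_bias += upd["hidden_bias"]
        _, c2 = bp.forward(net, x)
        assert bp.instance_error(c2, Y) < before


class TestTraining:
    def test_descent_on_separable_data(self, small_signal_dataset):
        cfg = bp.BpmllTrainConfig(alpha=0.05, max_epochs=8, M=8, seed=0)
        _, trace = bp.train_bpmll(small_signal_dataset, cfg)
        assert trace[-1] < trace[0]

    def test_deterministic_given_seed(self, small_signal_dataset):
        cfg = bp.BpmllTrainConfig(alpha=0.05, max_epochs=3, M=4, seed=5)
        n1, t1 = bp.train_bpmll(small_signal_dataset, cfg)
        n2, t2 = bp.train_bpmll(small_signal_dataset, cfg)
        assert np.array_equal(n1.V, n2.V) and t1 == t2

    def test_zero_learning_rate_stops_via_patience(self, small_signal_dataset, monkeypatch):
        """α→0 keeps E constant, so the first non-decrease fires patience=1
        and training stops after exactly 2 epochs."""
        cfg = bp.BpmllTrainConfig(alpha=1e-12, max_epochs=50, patience=1, M=3, seed=0)
        _, trace = bp.train_bpmll(small_signal_dataset, cfg)
        assert len(trace) == 3  # init + 2 epochs

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            bp.BpmllTrainConfig(alpha=1.5)

    def test_relabeling_invariance_of_global_error(self, rng):
        """Permuting label indices and output units together leaves E fixed."""
        net = bp.init_network(4, 3, 5, rng)
        X = rng.uniform(0, 1, (10, 4))
        labels = [frozenset({1, 4})] * 10
        ds = make_ds(X, labels, 5)
        perm = np.array([2, 0, 4, 1, 3])  # new index of old label j
        net_p = bp.BpmllNetwork(V=net.V.copy(), W=net.W[:, np.argsort(perm)],
                                hidden_bias=net.hidden_bias.copy(),
                                output_bias=net.output_bias[np.argsort(perm)])
        labels_p = [frozenset(int(perm[lab - 1]) + 1 for lab in y) for y in labels]
        ds_p = make_ds(X, labels_p, 5)
        e, _ = bp.global_error(net, ds)
        ep, _ = bp.global_error(net_p, ds_p)
        assert e == pytest.approx(ep, abs=1e-12)

    def test_feature_permutation_covariance(self, rng):
        """Permuting feature columns and V's rows together leaves the
        forward pass and every update covariant (identical up to the same
        permutation), hence identical error traces."""
        net = bp.init_network(5, 3, 4, rng)
        x = rng.uniform(0, 1, 5)
        perm = rng.permutation(5)
        net_p = bp.BpmllNetwork(V=net.V[perm], W=net.W.copy(),
                                hidden_bias=net.hidden_bias.copy(),
                                output_bias=net.output_bias.copy())
        _, c = bp.forward(net, x)
        _, c_p = bp.forward(net_p, x[perm])
        assert np.allclose(c, c_p, atol=1e-15)
        u = bp.gradients(net, x, {2}, alpha=0.1)
        u_p = bp.gradients(net_p, x[perm], {2}, alpha=0.1)
        assert np.allclose(u["V"][perm], u_p["V"], atol=1e-15)
        for k in ("W", "hidden_bias", "output_bias"):
            assert np.allclose(u[k], u_p[k], atol=1e-15)


class TestPrediction:
    def test_zero_net_scores_half_with_index_tiebreak(self):
        net = bp.BpmllNetwork(V=np.zeros((2, 2)), W=np.zeros((2, 3)),
                              hidden_bias=np.zeros(2), output_bias=np.zeros(3))
        pred = bp.predict_scores(net, np.random.rand(4, 2))
        assert np.all(pred.scores == 0.5)
        assert pred.ranks().tolist() == [[1, 2, 3]] * 4

    def test_output_bias_monotonicity(self, rng):
        """Raising θ_j strictly raises label j's scores and no other's."""
        net = bp.init_network(3, 4, 4, rng)
        X = rng.uniform(0, 1, (6, 3))
        before = bp.predict_scores(net, X).scores
        net.output_bias[2] += 0.3
        after = bp.predict_scores(net, X).scores
        assert np.all(after[:, 2] > before[:, 2])
        others = [0, 1, 3]
        assert np.array_equal(after[:, others], before[:, others])

    def test_predict_labels_threshold_and_top_t(self):
        rp = RankedPrediction(scores=[[0.9, 0.1], [0.2, 0.3]])
        assert bp.predict_labels(rp, "threshold") == [frozenset({1}), frozenset()]
        rp2 = RankedPrediction(scores=[[0.3, 0.2, 0.1]])
        assert bp.predict_labels(rp2, "top_t", t=2) == [frozenset({1, 2})]
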