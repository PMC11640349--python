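"""Reservoir construction, dynamics, ridge readout and tuning."""

import numpy as np
import pytest

import tdsliking as tl
from tdsliking.esn import (
    ESNResults,
    LeakyESN,
    ReservoirConfig,
    SearchSpace,
    tune,
)
from tdsliking.sensory_io import AttributeSet, TimeGrid

from conftest import random_curve_pairs


def one_neuron_model(alpha, input_col=0, attributes=None):
    """1-neuron reservoir with W=0, unit input weight on one channel, b=0."""
    cfg = ReservoirConfig(n_neurons=1, leaking_rate=alpha, seed=0,
                          reservoir_connectivity=1.0, input_connectivity=1.0)
    model = LeakyESN(cfg, attributes)
    model.W = np.zeros((1, 1))
    model.W_in = np.zeros((1, model.attributes.n))
    model.W_in[0, input_col] = 1.0
    model.b = np.zeros(1)
    return model


class TestConstruction:
    def test_exact_nonzero_counts(self):
        cfg = ReservoirConfig(n_neurons=128, reservoir_connectivity=0.05,
                              input_connectivity=0.05, seed=1)
        model = LeakyESN(cfg)
        assert np.count_nonzero(model.W) == round(0.05 * 128 * 128)  # 819
        assert np.count_nonzero(model.W_in) == round(0.05 * 128 * 8)

    def test_every_input_channel_connected(self):
        cfg = ReservoirConfig(n_neurons=128, input_connectivity=0.01, seed=2)
        model = LeakyESN(cfg)
        assert np.all(np.count_nonzero(model.W_in, axis=0) >= 1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_spectral_radius_exact(self, seed):
        model = LeakyESN(ReservoirConfig(seed=seed))
        radius = np.max(np.abs(np.linalg.eigvals(model.W)))
        assert radius == pytest.approx(0.90, abs=1e-8)

    def test_same_seed_bitwise_identical(self):
        a = LeakyESN(ReservoirConfig(seed=77))
        b = LeakyESN(ReservoirConfig(seed=77))
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.W_in, b.W_in)
        assert np.array_equal(a.b, b.b)


class TestDynamics:
    def test_zero_weights_give_zero_states(self):
        model = one_neuron_model(alpha=1.0)
        model.W_in[:] = 0.0
        u = np.random.default_rng(0).uniform(0, 1, size=(20, 8))
        assert np.all(model.states(u) == 0.0)

    def test_constant_input_fixed_point(self):
        # alpha=1, W=0: x(k) = tanh(u) immediately and forever
        model = one_neuron_model(alpha=1.0)
        u = np.zeros((10, 8))
        u[:, 0] = 1.0
        st = model.states(u)
        assert np.allclose(st[:, 0], np.tanh(1.0), atol=1e-12)

    def test_leaky_unrolled_recursion(self):
        # alpha=0.5: x1 = 0.5 tanh(1), x2 = 0.75 tanh(1)
        model = one_neuron_model(alpha=0.5)
        u = np.zeros((2, 8))
        u[:, 0] = 1.0
        st = model.states(u)
        assert st[0, 0] == pytest.approx(0.5 * np.tanh(1.0), abs=1e-12)
        assert st[1, 0] == pytest.approx(0.75 * np.tanh(1.0), abs=1e-12)

    def test_batched_states_match_sequential(self):
        model = LeakyESN(ReservoirConfig(n_neurons=16, seed=5))
        u = np.random.default_rng(1).uniform(0, 0.5, size=(4, 12, 8))
        batched = model.states(u)
        for i in range(4):
            assert np.allclose(batched[i], model.states(u[i]), atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        model = LeakyESN(ReservoirConfig(n_neurons=4, seed=0))
        with pytest.raises(ValueError):
            model.states(np.zeros((10, 5)))

    def test_fading_memory_contraction(self):
        # echo state property: different initial states converge under the
        # same drive (rho = 0.9, alpha = 1)
        cfg = ReservoirConfig(n_neurons=50, leaking_rate=1.0, seed=3)
        model = LeakyESN(cfg)
        rng = np.random.default_rng(0)
        u = rng.uniform(0, 1, size=(500, 8))
        x0 = rng.uniform(-1, 1, size=50)
        d0 = np.linalg.norm(x0)
        sa = model.states(u, x0=np.zeros(50))
        sb = model.states(u, x0=x0)
        assert np.linalg.norm(sa[-1] - sb[-1]) < 1e-6 * d0

    def test_slow_leak_distance_monotone(self):
        cfg = ReservoirConfig(n_neurons=30, leaking_rate=0.01, seed=4)
        model = LeakyESN(cfg)
        rng = np.random.default_rng(1)
        u = rng.uniform(0, 1, size=(200, 8))
        x0 = rng.uniform(-1, 1, size=30)
        da = model.states(u, x0=np.zeros(30))
        db = model.states(u, x0=x0)
        dist = np.linalg.norm(da - db, axis=1)
        assert np.all(np.diff(dist) <= 1e-12)


class TestReadout:
    def test_null_targets_give_zero_readout(self):
        pairs = random_curve_pairs(3, m=9, seed=0)
        for p in pairs:
            p.liking.values[:] = 0.0
        res = LeakyESN(ReservoirConfig(n_neurons=6, seed=0)).fit(pairs)
        assert np.allclose(res.readout, 0.0, atol=1e-12)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_independent_least_squares_oracle(self, trial):
        # augmented-system lstsq (SVD route) is the independent oracle for
        # ridge with an unpenalized intercept
        rng = np.random.default_rng(trial)
        n_neurons = int(rng.integers(2, 10))
        lam = float(rng.uniform(0.01, 3.0))
        cfg = ReservoirConfig(n_neurons=n_neurons, seed=trial,
                              ridge_coefficient=lam)
        pairs = random_curve_pairs(int(rng.integers(1, 4)), m=6, seed=trial + 100)
        model = LeakyESN(cfg)
        res = model.fit(pairs)
        X = model._design(np.stack([p.tds.proportions for p in pairs]))
        y = np.concatenate([p.liking.values for p in pairs])
        aug = np.sqrt(lam) * np.eye(X.shape[1])[:-1]  # intercept unpenalized
        Xa = np.vstack([X, aug])
        ya = np.concatenate([y, np.zeros(X.shape[1] - 1)])
        w_oracle = np.linalg.lstsq(Xa, ya, rcond=None)[0]
        assert np.allclose(res.readout, w_oracle, atol=1e-10)

    def test_matches_sklearn_ridge(self):
        from sklearn.linear_model import Ridge

        pairs = random_curve_pairs(2, m=8, seed=5)
        lam = 0.7
        model = LeakyESN(ReservoirConfig(n_neurons=5, seed=9,
                                         ridge_coefficient=lam))
        res = model.fit(pairs)
        X = model._design(np.stack([p.tds.proportions for p in pairs]))[:, :-1]
        y = np.concatenate([p.liking.values for p in pairs])
        sk = Ridge(alpha=lam, solver="cholesky").fit(X, y)
        assert np.allclose(res.readout[:-1], sk.coef_, atol=1e-8)
        assert res.readout[-1] == pytest.approx(sk.intercept_, abs=1e-8)

    def test_interpolation_with_zero_ridge(self):
        # square full-rank system: m=5 points, 4 neurons + intercept
        pairs = random_curve_pairs(1, m=5, seed=2)
        model = LeakyESN(ReservoirConfig(n_neurons=4, seed=2,
                                         ridge_coefficient=0.0))
        res = model.fit(pairs)
        pred = res.predict(pairs[0].tds)
        assert np.allclose(pred, pairs[0].liking.values, atol=1e-8)

    def test_scale_equivariance(self):
        pairs = random_curve_pairs(2, m=7, seed=3)
        half = random_curve_pairs(2, m=7, seed=3)
        for p in half:
            p.liking.values *= 0.5
        model = LeakyESN(ReservoirConfig(n_neurons=6, seed=1))
        w_full = model.fit(pairs).readout
        w_half = LeakyESN(ReservoirConfig(n_neurons=6, seed=1)).fit(half).readout
        assert np.allclose(0.5 * w_full, w_half, atol=1e-10)

    def test_predict_composes_states_and_dot(self):
        pairs = random_curve_pairs(2, m=9, seed=8)
        model = LeakyESN(ReservoirConfig(n_neurons=7, seed=8))
        res = model.fit(pairs)
        u = pairs[0].tds.proportions
        st = model.states(u)
        oracle = st @ res.readout[:-1] + res.readout[-1]
        assert np.allclose(res.predict(pairs[0].tds), oracle, atol=1e-12)

    def test_intercept_only_readout_constant_output(self):
        model = LeakyESN(ReservoirConfig(n_neurons=3, seed=0))
        res = ESNResults(model, np.array([0.0, 0.0, 0.0, 4.2]), TimeGrid(5), 1)
        assert np.allclose(res.predict(np.zeros((5, 8))), 4.2)

    def test_save_load_round_trip(self, tmp_path):
        pairs = random_curve_pairs(2, m=7, seed=4)
        res = LeakyESN(ReservoirConfig(n_neurons=6, seed=2)).fit(pairs)
        path = tmp_path / "model.npz"
        res.save(str(path))
        back = ESNResults.load(str(path))
        u = pairs[0].tds.proportions
        assert np.array_equal(back.predict(u), res.predict(u))
        assert back.config == res.config


class TestTuning:
    def test_budget_one_returns_single_sample(self):
        pairs = random_curve_pairs(3, m=7, seed=0)
        space = SearchSpace(budget=1, n_neurons=4, seed=11)
        res = tune(space, pairs[:2], pairs[2:])
        expect = space.sample(np.random.default_rng(11))
        assert res.config == expect

    def test_argmin_contract(self):
        pairs = random_curve_pairs(5, m=7, seed=1)
        train, val = pairs[:3], pairs[3:]
        space = SearchSpace(budget=6, n_neurons=4, seed=21)
        best = tune(space, train, val)
        rng = np.random.default_rng(21)
        losses = []
        for _ in range(6):
            cfg = space.sample(rng)
            losses.append(LeakyESN(cfg).fit(train).rmse(val))
        assert best.rmse(val) == pytest.approx(min(losses), abs=1e-12)

    def test_empty_validation_rejected(self):
        pairs = random_curve_pairs(2, m=7, seed=2)
        with pytest.raises(ValueError):
            tune(SearchSpace(budget=1), pairs, [])

    def test_yaml_search_space(self, tmp_path):
        cfgfile = tmp_path / "space.yml"
        cfgfile.write_text("input_scaling: [0.5, 1.0]\nridge_coefficient: 0.1\n")
        space = SearchSpace.from_yaml(str(cfgfile), budget=3, seed=0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = space.sample(rng)
            assert 0.5 <= c.input_scaling <= 1.0
            assert c.ridge_coefficient == 0.1

    def test_yaml_out_of_range_warns(self, tmp_path):
        cfgfile = tmp_path / "space.yml"
        cfgfile.write_text("bias_scaling: [0.01, 30.0]\n")
        with pytest.warns(UserWarning, match="bias_scaling"):
            SearchSpace.from_yaml(str(cfgfile))

    def test_sampled_configs_respect_ranges(self):
        space = SearchSpace(budget=1, seed=0)
        rng = np.random.default_rng(5)
        for _ in range(50):
            c = space.sample(rng)
            assert 0.01 <= c.input_scaling <= 1.43
            assert 0.03 <= c.bias_scaling <= 18.30
            assert 0.01 <= c.input_connectivity <= 0.10
            assert 0.05 <= c.reservoir_connectivity <= 0.88
            assert 0.01 <= c.ridge_coefficient <= 3.48
            assert c.leaking_rate == 0.01 and c.spectral_radius == 0.90
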