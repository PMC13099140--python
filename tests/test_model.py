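import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wakesleep.model import (
    CompartmentParams,
    DegenerateBatchError,
    NetworkConfig,
    basal_drive,
    branch_drive,
    compartment_forward,
    freeze_norms,
    init_network,
    interpolate,
    load_network,
    sample_sleep,
    sample_wake,
    save_network,
    top_variance_drive,
)


def make_compartment(width, fan_in, nb, seed=0, soma="norm"):
    p = CompartmentParams.create(width, fan_in, nb, np.random.default_rng(seed), soma=soma)
    p.branch_norm.mode = "frozen"
    if p.soma_norm is not None:
        p.soma_norm.mode = "frozen"
    return p


class TestBranchDrive:
    def test_zero_parameters_give_zero_output(self):
        p = make_compartment(3, 4, 2)
        p.W[...] = 0.0
        p.c[...] = 0.0
        out = branch_drive(p, np.random.default_rng(0).random((5, 4)), 0)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_affine_scale_zero_returns_shift(self):
        p = make_compartment(3, 4, 2)
        p.gamma[...] = 0.0
        p.beta[...] = 0.7
        out = branch_drive(p, np.random.default_rng(1).standard_normal((5, 4)), 1)
        assert np.allclose(out, 0.7)

    def test_identity_norm_reduces_to_tanh(self):
        from wakesleep.model import _NORM_EPS

        p = make_compartment(1, 1, 1)
        p.W[...] = 1.0
        p.c[...] = 0.0
        # stored variance chosen so the frozen normalization is the identity
        p.branch_norm.running_var[...] = 1.0 - _NORM_EPS
        out = branch_drive(p, np.array([[0.5]]), 0)
        assert out[0, 0] == pytest.approx(np.tanh(0.5), abs=1e-9)

    def test_branch_index_out_of_range(self):
        p = make_compartment(2, 3, 2)
        with pytest.raises(ValueError, match="branch_index"):
            branch_drive(p, np.zeros((2, 3)), 5)

    def test_input_shape_mismatch(self):
        p = make_compartment(2, 3, 2)
        with pytest.raises(ValueError, match="fan-in"):
            basal_drive(p, np.zeros((2, 7)))


class TestCompartmentDrive:
    def test_training_mode_output_standardized(self):
        # zero batch mean exactly; variance v/(v + eps), i.e. unit variance
        # up to the bounded normalization gain
        from wakesleep.model import _NORM_EPS

        p = make_compartment(6, 10, 3, seed=3)
        x = np.random.default_rng(4).standard_normal((256, 10))
        cache = compartment_forward(p, x, training=True)
        out = cache.out
        assert np.all(np.abs(out.mean(axis=0)) < 1e-6)
        assert np.all(np.abs(out.var(axis=0) - 1.0) < 0.05)
        v = cache.tanh_vt.var(axis=0)
        assert np.allclose(out.var(axis=0), v / (v + _NORM_EPS), atol=1e-9)

    def test_degenerate_batch_raises(self):
        p = make_compartment(2, 3, 2)
        with pytest.raises(DegenerateBatchError):
            basal_drive(p, np.zeros((1, 3)), training=True)

    def test_soma_input_linear_in_identical_branch_drives(self):
        # equal conductances and identical branch drives:
        # pre-normalization soma input = conductance * n_branches * drive + bias
        p = make_compartment(2, 3, 3, seed=5)
        p.W[:, 1:, :] = p.W[:, :1, :]  # all branches identical
        p.c[:, 1:] = p.c[:, :1]
        p.gamma[...] = 1.0
        p.beta[...] = 0.0
        p.rho[...] = p.rho[0, 0]
        x = np.random.default_rng(6).standard_normal((4, 3))
        cache = compartment_forward(p, x)
        w = p.conductance[0, 0]
        expected = w * 3 * cache.u[:, :, 0] + p.b
        assert np.allclose(cache.v_total, expected)

    def test_basal_apical_structural_symmetry(self):
        # the two pathways use the same compartment computation
        from wakesleep.model import apical_drive

        p = make_compartment(4, 5, 2, seed=7)
        x = np.random.default_rng(8).standard_normal((6, 5))
        assert np.array_equal(basal_drive(p, x), apical_drive(p, x))

    def test_drive_gradient_matches_finite_difference(self):
        # dh/dW via the analytic branch chain vs central differences
        from wakesleep.training import compartment_param_grads

        p = make_compartment(3, 4, 2, seed=9)
        x = np.random.default_rng(10).standard_normal((5, 4))
        i, n, j = 1, 0, 2
        unit = np.zeros((5, 3))
        unit[:, i] = 1.0  # dL/dout selects sum over batch of h_i
        cache = compartment_forward(p, x)
        g = unit * (1.0 - cache.tanh_vt**2) * cache.soma_inv_std
        analytic = compartment_param_grads(p, cache, g)["W"][i, n, j] * 5
        eps = 1e-6
        p.W[i, n, j] += eps
        hp = basal_drive(p, x)[:, i].sum()
        p.W[i, n, j] -= 2 * eps
        hm = basal_drive(p, x)[:, i].sum()
        p.W[i, n, j] += eps
        fd = (hp - hm) / (2 * eps)
        assert analytic == pytest.approx(fd, rel=1e-5)


class TestTopVarianceDrive:
    def test_zero_parameters_give_unit_variance(self):
        p = make_compartment(3, 4, 2, soma="exp")
        for name in ("W", "c", "rho", "b", "beta"):
            getattr(p, name)[...] = 0.0
        out = top_variance_drive(p, np.random.default_rng(0).random((5, 4)))
        assert np.allclose(out, 1.0)

    def test_positive_for_random_draws(self):
        rng = np.random.default_rng(1)
        for seed in range(20):
            p = make_compartment(3, 4, 2, seed=seed, soma="exp")
            p.W[...] = rng.standard_normal(p.W.shape) * 3
            p.b[...] = rng.standard_normal(3) * 3
            out = top_variance_drive(p, rng.standard_normal((500, 4)) * 2)
            assert np.all(out > 0)

    def test_exponential_soma(self):
        # doubling the soma input squares the output
        p = make_compartment(2, 3, 2, soma="exp")
        x = np.random.default_rng(2).standard_normal((4, 3))
        cache = compartment_forward(p, x)
        assert np.allclose(np.exp(2.0 * cache.v_total), cache.out**2)


class TestInterpolate:
    @pytest.mark.parametrize("kappa", [0.01, 0.35, 1.0, 1e6])
    def test_endpoint_identities(self, kappa):
        rng = np.random.default_rng(0)
        a = rng.uniform(-10, 10, 50)
        b = rng.uniform(-10, 10, 50)
        assert np.all(np.abs(interpolate(a, b, 0.0, kappa) - a) <= 1e-9)
        assert np.all(np.abs(interpolate(a, b, 1.0, kappa) - b) <= 1e-9)

    def test_equal_arguments_identity(self):
        x = np.linspace(-5, 5, 11)
        for alpha in (0.0, 0.3, 0.5, 1.0):
            assert np.allclose(interpolate(x, x, alpha, 0.35), x, atol=1e-9)

    def test_linear_limit_large_kappa(self):
        assert interpolate(1.0, 3.0, 0.5, 1e6) == pytest.approx(2.0, abs=1e-5)

    def test_max_limit_small_kappa(self):
        assert interpolate(1.0, 3.0, 0.5, 1e-4) == pytest.approx(3.0, abs=1e-3)

    def test_domain_error(self):
        with pytest.raises(ValueError, match="alpha"):
            interpolate(0.0, 1.0, 1.5, 0.35)
        with pytest.raises(ValueError, match="kappa"):
            interpolate(0.0, 1.0, 0.5, -1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        a=st.floats(-10, 10),
        da=st.floats(0, 5),
        b=st.floats(-10, 10),
        db=st.floats(0, 5),
        alpha=st.floats(0, 1),
        kappa=st.floats(0.05, 100),
    )
    def test_monotone_in_both_arguments(self, a, da, b, db, alpha, kappa):
        f0 = interpolate(a, b, alpha, kappa)
        assert interpolate(a + da, b, alpha, kappa) >= f0 - 1e-12
        assert interpolate(a, b + db, alpha, kappa) >= f0 - 1e-12


class TestSampling:
    def test_wake_matches_gaussian_moments(self, tiny_net, rng):
        stim = rng.random((1, 6)).repeat(10_000, axis=0)
        act = sample_wake(tiny_net, stim, rng)
        h = basal_drive(tiny_net.recognition[0], stim[:1])
        se = tiny_net.config.sigma_b / np.sqrt(10_000)
        assert np.all(np.abs(act.r[1].mean(axis=0) - h[0]) < 4 * se)
        assert np.allclose(act.r[1].var(axis=0), tiny_net.config.sigma_b**2, rtol=0.1)

    def test_wake_zero_noise_limit(self, rng):
        cfg = NetworkConfig(
            layer_widths=(4, 3), stimulus_dim=5, n_branches=2, sigma_b=1e-300, seed=3
        )
        net = init_network(cfg)
        freeze_norms(net)
        # force the variance head to (numerically) zero output
        net.h2.b[...] = -800.0
        stim = rng.random((4, 5))
        act = sample_wake(net, stim, rng)
        assert np.array_equal(act.r[0], stim)
        assert np.allclose(act.r[1], basal_drive(net.recognition[0], stim), atol=1e-12)

    def test_sleep_prior_moments(self, tiny_net, rng):
        act = sample_sleep(tiny_net, 10_000, rng)
        top = act.r[tiny_net.config.n_layers]
        assert np.all(np.abs(top.mean(axis=0)) < 4 / np.sqrt(10_000))
        assert np.allclose(top.var(axis=0), 1.0, rtol=0.1)

    def test_sleep_conditional_variance(self, tiny_net, rng):
        from wakesleep.model import apical_drive

        L = tiny_net.config.n_layers
        top = rng.standard_normal((1, tiny_net.config.widths[L])).repeat(5000, axis=0)
        mu = apical_drive(tiny_net.generative[L - 1], top[:1])
        draws = mu + tiny_net.config.sigma_p * rng.standard_normal(
            (5000, mu.shape[1])
        )
        assert np.allclose(draws.var(axis=0), tiny_net.config.sigma_p**2, rtol=0.15)


class TestSerialization:
    def test_round_trip_exact(self, trained_small, tmp_path):
        save_network(tmp_path / "ckpt", trained_small)
        loaded = load_network(tmp_path / "ckpt")
        for (name_a, pa), (name_b, pb) in zip(
            trained_small.compartments(), loaded.compartments()
        ):
            assert name_a == name_b
            for attr in ("W", "c", "rho", "b", "gamma", "beta", "sg", "sb"):
                assert np.array_equal(getattr(pa, attr), getattr(pb, attr))
            assert np.array_equal(
                pa.branch_norm.running_mean, pb.branch_norm.running_mean
            )
            assert pa.branch_norm.mode == pb.branch_norm.mode
        x = np.random.default_rng(0).random((8, 196))
        assert np.array_equal(
            basal_drive(trained_small.recognition[0], x),
            basal_drive(loaded.recognition[0], x),
        )


class TestConfigValidation:
    def test_rejects_nonpositive_noise(self):
        with pytest.raises(ValueError):
            NetworkConfig(sigma_b=0.0)

    def test_rejects_bad_widths(self):
        with pytest.raises(ValueError):
            NetworkConfig(layer_widths=(4, 0, 2))
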