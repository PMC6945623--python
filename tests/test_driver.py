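"""The alternating driver: initialization, masking, convergence,
epoch accounting and missing-entry insensitivity."""

import warnings

import numpy as np
import pytest

from conftest import nnls_oracle
from nmfkit import (FactorizationConfig, MaskSpec, RegularizationSpec,
                    TargetMatrix, epochs_to_reach, factorize, gen_lowrank,
                    initialize, normalize_columns)
from nmfkit.scd import build_system


class TestInitialize:
    def test_same_seed_same_draw(self):
        cfg = FactorizationConfig(k=3, seed=11)
        W1, H1 = initialize(cfg, 10, 7)
        W2, H2 = initialize(cfg, 10, 7)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(H1, H2)
        assert W1.shape == (10, 3) and H1.shape == (3, 7)
        assert W1.min() >= 0 and H1.min() >= 0

    def test_masked_column_stamped_from_init(self, rng):
        profile = rng.uniform(size=10)
        init_W = rng.uniform(size=(10, 3))
        init_W[:, 0] = profile
        fixed = np.zeros((10, 3), dtype=bool)
        fixed[:, 0] = True
        cfg = FactorizationConfig(k=3, seed=0, init_W=init_W,
                                  mask=MaskSpec(fixed_W=fixed))
        W, _ = initialize(cfg, 10, 7)
        np.testing.assert_array_equal(W[:, 0], profile)

    def test_masked_entries_default_to_zero_without_init(self):
        fixed = np.zeros((6, 2), dtype=bool)
        fixed[0:3, 1] = True
        cfg = FactorizationConfig(k=2, seed=0, mask=MaskSpec(fixed_W=fixed))
        W, _ = initialize(cfg, 6, 4)
        assert (W[0:3, 1] == 0).all()
        assert (W[~fixed] > 0).all()

    def test_lee_warns_on_zero_init(self):
        init_H = np.ones((2, 4))
        init_H[0, 0] = 0.0
        cfg = FactorizationConfig(k=2, algorithm="lee", seed=0, init_H=init_H)
        with pytest.warns(UserWarning, match="zero"):
            initialize(cfg, 5, 4)

    def test_overparameterized_rank_warns(self):
        with pytest.warns(UserWarning, match="over-parameterized"):
            initialize(FactorizationConfig(k=9, seed=0), 5, 4)

    def test_negative_user_init_rejected(self):
        cfg = FactorizationConfig(k=2, seed=0, init_W=-np.ones((5, 2)))
        with pytest.raises(ValueError):
            initialize(cfg, 5, 4)


class TestFactorize:
    def test_exact_low_rank_recovered_to_numerical_precision(self):
        sample = gen_lowrank(30, 20, 2, noise_sd=0.0, seed=0)
        cfg = FactorizationConfig(k=2, seed=1, n_inner=2, max_epochs=4000,
                                  rel_tol=1e-15)
        res = factorize(sample.A, cfg)
        assert res.final_loss < 1e-8

    def test_exact_low_rank_with_missing_entries(self):
        sample = gen_lowrank(60, 40, 3, noise_sd=0.0, missing_frac=0.3, seed=3)
        cfg = FactorizationConfig(k=3, seed=2, n_inner=2, max_epochs=4000,
                                  rel_tol=1e-15)
        res = factorize(sample.A, cfg)
        assert res.final_loss < 1e-4

    def test_fully_masked_W_reduces_to_nnls(self, rng):
        """Fixing all of W turns the run into a pure H-solve whose
        converged columns match the brute-force QP oracle."""
        W_true = rng.uniform(0.2, 1, size=(8, 2))
        A = TargetMatrix(rng.uniform(0.5, 3, size=(8, 5)))
        fixed = np.ones((8, 2), dtype=bool)
        cfg = FactorizationConfig(k=2, seed=4, init_W=W_true,
                                  mask=MaskSpec(fixed_W=fixed),
                                  n_inner=2000, max_epochs=10000,
                                  rel_tol=1e-14)
        res = factorize(A, cfg)
        np.testing.assert_array_equal(res.W, W_true)
        system = build_system(A, W_true, (0.0, 0.0, 0.0))
        for j in range(5):
            expected = nnls_oracle(np.asarray(system.V), system.U[:, j])
            np.testing.assert_allclose(res.H[:, j], expected, atol=1e-8)

    @pytest.mark.parametrize("algorithm", ["scd", "lee"])
    def test_mse_loss_trace_monotone(self, algorithm):
        sample = gen_lowrank(40, 25, 3, noise_sd=0.5, seed=7)
        cfg = FactorizationConfig(k=4, algorithm=algorithm, seed=8,
                                  max_epochs=150, rel_tol=1e-15)
        res = factorize(sample.A, cfg)
        diffs = np.diff(res.loss_trace)
        assert (diffs <= 1e-12 * np.maximum(1.0, res.loss_trace[:-1])).all()

    def test_trace_length_and_convergence_fields(self):
        sample = gen_lowrank(30, 20, 2, noise_sd=0.3, seed=9)
        cfg = FactorizationConfig(k=2, seed=10, n_inner=2, max_epochs=500,
                                  rel_tol=1e-3)
        res = factorize(sample.A, cfg)
        assert len(res.loss_trace) == res.epochs_run
        assert len(res.objective_trace) == res.epochs_run
        assert res.converged
        assert res.final_rel_change < 1e-3

    def test_unobserved_values_never_influence_results(self, rng):
        sample = gen_lowrank(40, 25, 3, noise_sd=0.5, missing_frac=0.25,
                             seed=11)
        A1 = sample.A
        scrambled = A1.values.copy()
        scrambled[~A1.observed] = rng.uniform(0, 1e3,
                                              size=(~A1.observed).sum())
        A2 = TargetMatrix(scrambled, A1.observed)
        for algorithm, loss in [("scd", "mse"), ("scd", "mkl"),
                                ("lee", "mse"), ("lee", "mkl")]:
            cfg = FactorizationConfig(k=3, algorithm=algorithm, loss=loss,
                                      seed=12, max_epochs=60)
            r1, r2 = factorize(A1, cfg), factorize(A2, cfg)
            np.testing.assert_array_equal(r1.W, r2.W)
            np.testing.assert_array_equal(r1.H, r2.H)
            np.testing.assert_array_equal(r1.loss_trace, r2.loss_trace)

    def test_reaching_time_helper(self):
        sample = gen_lowrank(30, 20, 2, noise_sd=0.5, seed=13)
        cfg = FactorizationConfig(k=2, seed=14, max_epochs=300, rel_tol=1e-15)
        res = factorize(sample.A, cfg)
        assert epochs_to_reach(res, res.loss_trace[-1]) <= res.epochs_run
        assert epochs_to_reach(res, -1.0) is None

    def test_plain_array_input_is_wrapped(self, rng):
        A = rng.uniform(0.5, 2, size=(10, 6))
        res = factorize(A, FactorizationConfig(k=2, seed=0, max_epochs=50))
        assert res.W.shape == (10, 2)


def test_normalize_columns_preserves_product(rng):
    W = rng.uniform(0, 2, size=(8, 3))
    W[:, 2] = 0.0  # degenerate column left untouched
    H = rng.uniform(0, 2, size=(3, 5))
    Wn, Hn = normalize_columns(W, H)
    np.testing.assert_allclose(Wn @ Hn, W @ H, rtol=1e-12)
    np.testing.assert_allclose(Wn[:, :2].sum(axis=0), 1.0)


def test_config_validation():
    with pytest.raises(ValueError):
        FactorizationConfig(k=0)
    with pytest.raises(ValueError):
        FactorizationConfig(k=2, algorithm="nope")
    with pytest.raises(ValueError):
        FactorizationConfig(k=2, rel_tol=0.0)
    with pytest.raises(ValueError):
        # SCD positivity condition enforced at config time
        FactorizationConfig(k=2, reg=RegularizationSpec(beta1=0.1, beta2=0.2))


def test_config_round_trips_through_dict():
    cfg = FactorizationConfig(k=4, algorithm="lee", loss="mkl",
                              reg=RegularizationSpec(1, 0, 2, 3, 0, 4),
                              n_inner=7, max_epochs=123, rel_tol=1e-5,
                              seed=99)
    back = FactorizationConfig.from_dict(cfg.to_dict())
    assert back.to_dict() == cfg.to_dict()
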