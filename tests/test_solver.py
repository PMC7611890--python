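"""ADMM solver: hard thresholding, z-update, stopping rule, convergence."""

import numpy as np
import pytest
import scipy.linalg
import scipy.sparse.linalg

import txlr
from txlr.hankel import build_hankel_tensor, fold, hankel_shape, multiplicity_map, unfold
from txlr.solver import data_consistency_update, svt_hard

from conftest import random_kspace


class TestSvtHard:
    def test_rank_at_least_min_dim_is_identity(self):
        a = random_kspace((6, 9), seed=0)
        assert np.allclose(svt_hard(a, 6), a)
        assert np.allclose(svt_hard(a, 100), a)

    def test_rank_one_outer_product_exact(self):
        rng = np.random.default_rng(1)
        a = np.outer(rng.standard_normal(7) + 1j, rng.standard_normal(5) + 1j)
        assert np.allclose(svt_hard(a, 1), a)

    @pytest.mark.parametrize("shape,r", [((8, 12), 3), ((12, 8), 3)])
    def test_eckart_young_error(self, shape, r):
        # Frobenius error equals the energy of the discarded singular values
        a = random_kspace(shape, seed=3)
        s = scipy.linalg.svd(a, compute_uv=False)
        err = np.linalg.norm(a - svt_hard(a, r))
        assert err == pytest.approx(np.sqrt((s[r:] ** 2).sum()), rel=1e-10)

    def test_large_matrix_path_matches_full_svd_oracle(self):
        # the Gram-eigendecomposition route used in the solver loop
        a = random_kspace((200, 1600), seed=4)
        u, s, vh = scipy.linalg.svd(a, full_matrices=False)
        oracle = (u[:, :50] * s[:50]) @ vh[:50]
        got = svt_hard(a, 50)
        assert np.linalg.norm(got - oracle) <= 1e-10 * np.linalg.norm(a)

    def test_output_rank_bounded(self):
        a = random_kspace((30, 40), seed=5)
        s = scipy.linalg.svd(svt_hard(a, 4), compute_uv=False)
        assert np.all(s[4:] <= 1e-10 * s[0])

    def test_non_finite_rejected(self):
        a = np.full((3, 3), np.nan)
        with pytest.raises(FloatingPointError):
            svt_hard(a, 1)


def cg_zupdate_oracle(d, mask, consensus, duals, rho, kernel):
    """Solve the z-update normal equations by conjugate gradients,
    applying T and T* as operators (no multiplicity shortcut)."""
    grid, shape = d.shape[:2], d.shape
    dims = hankel_shape(grid, kernel) + shape[2:]
    m4 = mask.astype(float)[:, :, None, :]

    def matvec(v):
        z = v.reshape(shape)
        out = m4 * z
        for _ in consensus:
            out = out + rho * txlr.adjoint_hankel(
                build_hankel_tensor(z, kernel), grid, kernel
            )
        return out.ravel()

    rhs = m4 * d
    for tag, c in consensus.items():
        rhs = rhs + rho * txlr.adjoint_hankel(
            fold(c + duals[tag], dims, tag), grid, kernel
        )
    n = d.size
    op = scipy.sparse.linalg.LinearOperator((n, n), matvec=matvec,
                                            dtype=complex)
    sol, info = scipy.sparse.linalg.cg(op, rhs.ravel(), rtol=1e-12,
                                       maxiter=5000)
    assert info == 0
    return sol.reshape(shape)


class TestDataConsistency:
    def _setup(self, seed=0, two_constraints=True):
        shape, kernel = (4, 4, 2, 2), (2, 2)
        d = random_kspace(shape, seed=seed)
        rng = np.random.default_rng(seed + 50)
        mask = (rng.random((4, 4, 2)) < 0.6).astype(np.uint8)
        mask[2, 2] = 1
        dims = hankel_shape((4, 4), kernel) + (2, 2)
        tags = ("TC", "RC") if two_constraints else ("RC",)
        cons = {t: unfold(random_kspace(dims, seed=seed + i), t)
                for i, t in enumerate(tags)}
        duals = {t: unfold(random_kspace(dims, seed=seed + 10 + i), t)
                 for i, t in enumerate(tags)}
        return d, mask, cons, duals, kernel

    @pytest.mark.parametrize("two", [True, False])
    def test_matches_conjugate_gradient_oracle(self, two):
        d, mask, cons, duals, kernel = self._setup(two_constraints=two)
        rho = 0.37
        z = data_consistency_update(d * mask[:, :, None, :], mask, cons,
                                    duals, rho, kernel)
        oracle = cg_zupdate_oracle(d * mask[:, :, None, :], mask, cons,
                                   duals, rho, kernel)
        assert np.linalg.norm(z - oracle) <= 1e-8 * np.linalg.norm(oracle)

    def test_full_sampling_consensus_at_truth_is_fixed_point(self):
        d = random_kspace((5, 5, 2, 2), seed=1)
        mask = np.ones((5, 5, 2), dtype=np.uint8)
        h = build_hankel_tensor(d, (2, 2))
        cons = {t: unfold(h, t) for t in ("TC", "RC")}
        duals = {t: np.zeros_like(c) for t, c in cons.items()}
        z = data_consistency_update(d, mask, cons, duals, 0.5, (2, 2))
        assert np.allclose(z, d, atol=1e-12)

    def test_large_rho_returns_consensus_average(self):
        d, mask, cons, duals, kernel = self._setup(seed=2)
        duals = {t: np.zeros_like(v) for t, v in duals.items()}
        mult = multiplicity_map((4, 4), kernel)
        z = data_consistency_update(d * mask[:, :, None, :], mask, cons,
                                    duals, 1e12, kernel)
        dims = hankel_shape((4, 4), kernel) + (2, 2)
        avg = sum(
            txlr.adjoint_hankel(fold(c, dims, t), (4, 4), kernel)
            for t, c in cons.items()
        ) / (2 * mult[:, :, None, None])
        assert np.allclose(z, avg, atol=1e-8 * np.abs(avg).max())

    def test_zero_rho_with_unsampled_points_rejected(self):
        d, mask, cons, duals, kernel = self._setup()
        mask[0, 0] = 0
        with pytest.raises(ValueError, match="rho"):
            data_consistency_update(d, mask, cons, duals, 0.0, kernel)


class TestChiSquare:
    def test_perfect_fit_is_zero(self):
        d = random_kspace((6, 6, 2, 2), seed=0)
        mask = np.ones((6, 6, 2), dtype=np.uint8)
        noise = txlr.NoiseModel(sd=np.ones(2))
        assert txlr.chi_square_statistic(d, d, mask, noise) == 0.0

    def test_zero_estimate_far_exceeds_one(self):
        d = 10 * random_kspace((6, 6, 2, 2), seed=1)
        mask = np.ones((6, 6, 2), dtype=np.uint8)
        noise = txlr.NoiseModel(sd=np.full(2, 0.01))
        assert txlr.chi_square_statistic(np.zeros_like(d), d, mask, noise) > 100

    def test_truth_vs_noisy_data_near_one(self, study_dataset):
        clean, noisy = study_dataset["clean"], study_dataset["noisy"]
        noise = study_dataset["noise"]
        mask = np.ones(clean.shape[:2] + (clean.shape[3],), dtype=np.uint8)
        nu = mask.sum() * clean.shape[2]
        stat = txlr.chi_square_statistic(clean, noisy, mask, noise)
        assert abs(stat - 1) <= 3 / np.sqrt(nu)

    def test_zero_sd_rejected(self):
        d = random_kspace((4, 4, 1, 1), seed=0)
        mask = np.ones((4, 4, 1), dtype=np.uint8)
        with pytest.raises(ValueError, match="positive"):
            txlr.chi_square_statistic(d, d, mask, txlr.NoiseModel(sd=[0.0]))


def reference_admm(d, mask, kernel, ranks, rho, iters, tags=("TC", "RC")):
    """Literal transcription of the unrelaxed fixed-penalty iteration:
    consensus SVT, exact z minimiser, dual ascent."""
    grid = d.shape[:2]
    dims = hankel_shape(grid, kernel) + d.shape[2:]
    mult = multiplicity_map(grid, kernel)
    m4 = mask.astype(float)[:, :, None, :]
    z = np.zeros_like(d)
    y = {t: np.zeros(unfold(np.empty(dims, complex), t).shape, complex)
         for t in tags}
    for _ in range(iters):
        h = build_hankel_tensor(z, kernel)
        c = {t: svt_hard(unfold(h, t) - y[t], r) for t, r in zip(tags, ranks)}
        num = m4 * d
        for t in tags:
            num = num + rho * txlr.adjoint_hankel(
                fold(c[t] + y[t], dims, t), grid, kernel)
        z = num / (m4 + len(tags) * rho * mult[:, :, None, None])
        h = build_hankel_tensor(z, kernel)
        for t in tags:
            y[t] = y[t] + c[t] - unfold(h, t)
    return z


class TestRunAdmm:
    def test_matches_textbook_admm_when_unrelaxed(self):
        # alpha = 1, tau = 1 reduces to the plain scaled-ADMM iteration
        d = random_kspace((6, 6, 2, 2), seed=0)
        rng = np.random.default_rng(99)
        mask = (rng.random((6, 6, 2)) < 0.7).astype(np.uint8)
        mask[3, 3] = 1
        cfg = txlr.ReconConfig(method="txlr", kernel=(3, 3), ranks=4,
                               max_iters=12, alpha=1.0, tau=1.0, rho0=1e-3)
        z, _ = txlr.run_admm(d, mask, cfg)
        ref = reference_admm(d * mask[:, :, None, :], mask, (3, 3), (4, 4),
                             1e-3, 12)
        assert np.linalg.norm(z - ref) <= 1e-10 * np.linalg.norm(ref)

    def test_noiseless_fully_sampled_recovery(self, study_dataset):
        clean = study_dataset["clean"]
        mask = np.ones(clean.shape[:2] + (clean.shape[3],), dtype=np.uint8)
        z, log = txlr.run_admm(clean, mask, txlr.ReconConfig(method="txlr"),
                               truth=clean)
        assert log[-1]["rmse"] < 1e-3

    def test_noiseless_r4_recovery(self, study_dataset):
        clean = study_dataset["clean"]
        mask = txlr.poisson_disc_mask(24, 24, 8, 4, seed=2)
        z, log = txlr.run_admm(clean * mask[:, :, None, :], mask,
                               txlr.ReconConfig(method="txlr"), truth=clean)
        assert log[-1]["rmse"] < 0.05

    def test_misfit_trend_and_log_fields(self, study_dataset):
        clean, noisy = study_dataset["clean"], study_dataset["noisy"]
        mask = txlr.poisson_disc_mask(24, 24, 8, 4, seed=3)
        z, log = txlr.run_admm(noisy * mask[:, :, None, :], mask,
                               txlr.ReconConfig(method="txlr"),
                               noise=study_dataset["noise"], truth=clean)
        assert {"iter", "misfit", "rho", "chi2", "rmse"} <= set(log[0])
        assert log[-1]["rmse"] < log[0]["rmse"]

    def test_consensus_rank_constraint_holds(self):
        # after the SVT step every active unfolding has rank <= r
        d = random_kspace((8, 8, 2, 2), seed=4)
        mask = txlr.poisson_disc_mask(8, 8, 2, 2, seed=0)
        cfg = txlr.ReconConfig(method="txlr", kernel=(3, 3), ranks=3,
                               max_iters=5)
        z, _ = txlr.run_admm(d, mask, cfg)
        h = build_hankel_tensor(z, (3, 3))
        for tag in ("TC", "RC"):
            s = scipy.linalg.svd(svt_hard(unfold(h, tag), 3),
                                 compute_uv=False)
            assert np.all(s[3:] <= 1e-10 * s[0])

    def test_chi2_stop_halts_early(self, study_dataset):
        clean, noisy = study_dataset["clean"], study_dataset["noisy"]
        mask = txlr.poisson_disc_mask(24, 24, 8, 2, seed=4)
        cfg = txlr.ReconConfig(method="txlr", stop="chi2", max_iters=50)
        z, log = txlr.run_admm(noisy * mask[:, :, None, :], mask, cfg,
                               noise=study_dataset["noise"])
        assert log[-1]["chi2"] <= 1.0
        assert all(e["chi2"] > 1.0 for e in log[:-1])

    def test_chi2_stop_requires_noise_model(self):
        d = random_kspace((6, 6, 1, 1), seed=0)
        mask = np.ones((6, 6, 1), dtype=np.uint8)
        cfg = txlr.ReconConfig(stop="chi2")
        with pytest.raises(ValueError, match="NoiseModel"):
            txlr.run_admm(d, mask, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            txlr.ReconConfig(method="nope")
        with pytest.raises(ValueError):
            txlr.ReconConfig(alpha=2.5)
        with pytest.raises(ValueError):
            txlr.ReconConfig(ranks=0)
        with pytest.raises(ValueError):
            txlr.ReconConfig(method="vc", ranks=(1, 2))
        assert txlr.ReconConfig(method="txlr").iters == 50
        assert txlr.ReconConfig(method="vc").iters == 100
        assert txlr.ReconConfig(method="primo").unfoldings == ("RC",)
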