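"""Forward SDE: VP coefficients, transition kernels, conditional scores, prior."""

import numpy as np
import pytest
from scipy import integrate, stats

from molsde.mol_data import FixtureSpec, MoleculeBatch, make_fixtures
from molsde.sde import (
    DiffusionSpec,
    NoiseSchedule,
    conditional_score_target,
    drift_diffusion,
    perturb,
    sample_prior,
    vp_coefficients,
)


class TestVPCoefficients:
    def test_no_perturbation_at_t0(self, spec):
        alpha, sigma = vp_coefficients(0.0, spec.schedule_x)
        assert alpha == pytest.approx(1.0)
        assert sigma == pytest.approx(0.0)

    def test_alpha_matches_numerical_quadrature(self):
        sched = NoiseSchedule(beta_min=0.1, beta_max=20.0, T=1.0)
        for t in (0.3, 0.7, 1.0):
            integral, _ = integrate.quad(sched.beta, 0.0, t)
            alpha, _ = vp_coefficients(t, sched)
            assert alpha == pytest.approx(np.exp(-0.5 * integral), abs=1e-8)
        # closed form at T: alpha_T = exp(-(beta_min + (beta_max-beta_min)/2)/2)
        alpha_T, _ = vp_coefficients(1.0, sched)
        assert alpha_T == pytest.approx(np.exp(-5.025), rel=1e-12)

    def test_variance_preserving_identity(self, rng):
        sched = NoiseSchedule()
        t = rng.uniform(0, 1, size=100)
        alpha, sigma = sched.alpha_sigma(t)
        assert np.allclose(alpha**2 + sigma**2, 1.0, atol=1e-12)
        assert np.all(np.diff(sched.alpha_sigma(np.linspace(0.01, 1, 50))[0]) < 0)

    def test_time_domain_enforced(self):
        with pytest.raises(ValueError):
            vp_coefficients(1.5, NoiseSchedule())

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            NoiseSchedule(beta_min=2.0, beta_max=1.0)


class TestDriftDiffusion:
    def test_drift_linear_in_state(self, rng):
        sched = NoiseSchedule()
        u = rng.standard_normal((4, 3))
        f0, _ = drift_diffusion(0.5, np.zeros_like(u), sched)
        f1, _ = drift_diffusion(0.5, u, sched)
        f2, _ = drift_diffusion(0.5, 2 * u, sched)
        assert np.allclose(f0, 0.0)
        assert np.allclose(f2, 2 * f1)

    def test_vp_diffusion_identity_by_finite_differences(self):
        # g^2 = d sigma^2/dt - 2 (d log alpha/dt) sigma^2 must equal beta(t)
        sched = NoiseSchedule()
        h = 1e-6
        for t in (0.2, 0.5, 0.9):
            a_p, s_p = sched.alpha_sigma(t + h)
            a_m, s_m = sched.alpha_sigma(t - h)
            dsigma2 = (s_p**2 - s_m**2) / (2 * h)
            dlogalpha = (np.log(a_p) - np.log(a_m)) / (2 * h)
            _, sigma = sched.alpha_sigma(t)
            g2 = dsigma2 - 2 * dlogalpha * sigma**2
            _, g = drift_diffusion(t, 0.0, sched)
            assert g2 == pytest.approx(g**2, rel=1e-6)


class TestPerturb:
    def test_t0_returns_data_exactly(self, fixture_batch, spec, rng):
        state = perturb(fixture_batch, 0.0, spec, rng)
        assert np.array_equal(state.X, fixture_batch.X)
        assert np.array_equal(state.A, fixture_batch.A)

    def test_small_t_stays_near_data(self, fixture_batch, spec, rng):
        state = perturb(fixture_batch, 1e-6, spec, rng)
        assert np.max(np.abs(state.X - fixture_batch.X)) < 0.05

    def test_com_free_and_symmetric_for_any_draw(self, fixture_batch, spec, rng):
        state = perturb(fixture_batch, 0.5, spec, rng)
        coms = (state.P * state.mask[..., None]).sum(axis=1)
        assert np.max(np.abs(coms)) < 1e-9
        assert np.array_equal(state.A, np.swapaxes(state.A, 1, 2))
        assert np.all(np.diagonal(state.A, axis1=1, axis2=2) == 0)
        assert np.all(state.X * (1 - state.mask[..., None]) == 0)

    def test_gaussian_moments_match_kernel(self, spec, rng):
        mols = make_fixtures(FixtureSpec(templates=("methane",),
                                         count_per_template=1, jitter_std=0.0,
                                         seed=0))
        batch = MoleculeBatch.from_molecules(mols)
        t = 0.4
        alpha, sigma = spec.schedule_x.alpha_sigma(t)
        draws = np.stack([perturb(batch, t, spec, rng).X for _ in range(10_000)])
        mean_err = np.abs(draws.mean(axis=0) - alpha * batch.X)
        se_mean = sigma / np.sqrt(10_000)
        assert np.max(mean_err) < 4 * se_mean
        std = draws.std(axis=0)
        se_std = sigma / np.sqrt(2 * 10_000)
        assert np.max(np.abs(std - sigma)) < 4 * se_std

    def test_kernel_factorizes_across_components(self, spec, rng):
        # joint transition log-density = sum of the three component terms
        mols = make_fixtures(FixtureSpec(templates=("water",),
                                         count_per_template=1, jitter_std=0.0,
                                         seed=0))
        batch = MoleculeBatch.from_molecules(mols)
        t = 0.6
        state = perturb(batch, t, spec, rng)

        n = 3
        iu = np.triu_indices(n, k=1)
        ax, sx = spec.schedule_x.alpha_sigma(t)
        aa, sa = spec.schedule_a.alpha_sigma(t)
        # joint: one multivariate normal over the concatenated free entries
        u = np.concatenate([state.X[0].ravel(), state.A[0][iu]])
        mu = np.concatenate([ax * batch.X[0].ravel(), aa * batch.A[0][iu]])
        sd = np.concatenate([np.full(batch.X[0].size, sx), np.full(len(iu[0]), sa)])
        joint = stats.multivariate_normal.logpdf(u, mean=mu, cov=np.diag(sd**2))
        parts = (
            stats.norm.logpdf(state.X[0].ravel(), ax * batch.X[0].ravel(), sx).sum()
            + stats.norm.logpdf(state.A[0][iu], aa * batch.A[0][iu], sa).sum()
        )
        assert joint == pytest.approx(parts, rel=1e-10)

    def test_rotation_commutes_in_distribution(self, spec):
        # moments of perturb(R P0) match R @ moments of perturb(P0)
        mols = make_fixtures(FixtureSpec(templates=("water",),
                                         count_per_template=1, jitter_std=0.0,
                                         seed=0))
        batch = MoleculeBatch.from_molecules(mols)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rot = MoleculeBatch(X=batch.X, P=batch.P @ R.T, A=batch.A, mask=batch.mask)
        t = 0.5
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        m1 = np.mean([perturb(batch, t, spec, rng1).P for _ in range(10_000)], axis=0)
        m2 = np.mean([perturb(rot, t, spec, rng2).P for _ in range(10_000)], axis=0)
        sigma = spec.schedule_p.alpha_sigma(t)[1]
        assert np.max(np.abs(m1 @ R.T - m2)) < 4 * sigma / np.sqrt(10_000) + 1e-12


class TestConditionalScore:
    def test_zero_noise_gives_zero_target(self, fixture_batch, spec):
        t = 0.3
        state = perturb(fixture_batch, t, spec, np.random.default_rng(0))
        for name, sched in (("X", spec.schedule_x), ("P", spec.schedule_p),
                            ("A", spec.schedule_a)):
            alpha, _ = sched.alpha_sigma(t)
            setattr(state, name, alpha * getattr(fixture_batch, name))
        target = conditional_score_target(fixture_batch, state, spec)
        assert np.allclose(target.X, 0.0)
        assert np.allclose(target.P, 0.0)
        assert np.allclose(target.A, 0.0)

    def test_scalar_example(self):
        # alpha=0.8, sigma=0.6, x0=1, x_t=0.5 -> -(0.5-0.8)/0.36 = +0.8333...
        assert -(0.5 - 0.8 * 1.0) / 0.6**2 == pytest.approx(0.83333, abs=1e-5)

    def test_matches_numerical_gradient_of_log_density(self):
        from molsde.selftest import conditional_score_vs_numerical

        assert conditional_score_vs_numerical(n_points=20, seed=1) < 1e-6

    def test_undefined_at_t0(self, fixture_batch, spec, rng):
        state = perturb(fixture_batch, 0.5, spec, rng)
        state.t = np.zeros_like(state.t)
        with pytest.raises(ValueError):
            conditional_score_target(fixture_batch, state, spec)


class TestPrior:
    def test_structure(self, spec, rng):
        state = sample_prior(6, 5, spec, rng, n_samples=8)
        assert np.max(np.abs(state.P.sum(axis=1))) < 1e-9
        assert np.array_equal(state.A, np.swapaxes(state.A, 1, 2))
        assert np.all(np.diagonal(state.A, axis1=1, axis2=2) == 0)

    def test_entry_variances(self, spec, rng):
        n = 6
        state = sample_prior(n, 5, spec, rng, n_samples=10_000)
        se = 3 / np.sqrt(2 * 10_000)
        assert abs(state.X.var() - 1.0) < 3 * se
        iu = np.triu_indices(n, k=1)
        assert abs(state.A[:, iu[0], iu[1]].var() - 1.0) < 3 * se
        # projected coordinate entries have variance (N-1)/N
        assert abs(state.P.var() - (n - 1) / n) < 3 * se


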