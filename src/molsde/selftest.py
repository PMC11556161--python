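"""Oracle-style self-checks: equivariance battery, score oracle, solver oracle.

These checks validate the framework's structural guarantees independently
of any learned weights: the E(3)/permutation symmetry contracts of the
score networks, the conditional-score formula against numerical
differentiation of the Gaussian transition log-density, convergence of the
forward diffusion to the prior, and the Predictor-Corrector solver against
a closed-form 1-D Gaussian target.  The CLI ``selftest`` command runs
trimmed versions; the test suite and the acceptance script run them at
full size.
"""

from __future__ import annotations

import numpy as np

from .mol_data import FixtureSpec, MoleculeBatch, make_fixtures
from .nets import NetworkConfig, ScoreModel
from .sampling import SamplerConfig, pc_sample
from .sde import (
    DiffusionSpec,
    NoisedState,
    PartialScores,
    conditional_score_target,
    perturb,
    project_p_noise,
    sample_prior,
    symmetrize_offdiag,
)
from .vocab import DEFAULT_VOCABULARY

__all__ = [
    "random_orthogonal",
    "random_state",
    "equivariance_battery",
    "conditional_score_vs_numerical",
    "forward_convergence_moments",
    "solver_gaussian_moments",
    "run_selftest",
]


def random_orthogonal(rng: np.random.Generator, reflect: bool | None = None) -> np.ndarray:
    """Haar-ish random 3x3 orthogonal matrix; reflect=None mixes both cosets."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    want_reflection = rng.random() < 0.5 if reflect is None else reflect
    if (np.linalg.det(q) < 0) != want_reflection:
        q[:, 0] = -q[:, 0]
    return q


def random_state(
    rng: np.random.Generator, n_atoms: int = 4, k: int | None = None, t: float = 0.5
) -> NoisedState:
    """A generic noised state: random X, CoM-free P, symmetric zero-diag A."""
    k = k or DEFAULT_VOCABULARY.k
    mask = np.ones((1, n_atoms))
    X = rng.standard_normal((1, n_atoms, k))
    P = project_p_noise(rng.standard_normal((1, n_atoms, 3)), mask)
    A = symmetrize_offdiag(rng.standard_normal((1, n_atoms, n_atoms)))
    return NoisedState(X=X, P=P, A=A, t=np.array([t]), mask=mask)


def _transform_state(state: NoisedState, R: np.ndarray, perm: np.ndarray) -> NoisedState:
    return NoisedState(
        X=state.X[:, perm, :],
        P=state.P[:, perm, :] @ R,
        A=state.A[:, perm][:, :, perm],
        t=state.t.copy(),
        mask=state.mask[:, perm],
    )


def _rel_err(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.max(np.abs(a - b)) / (np.max(np.abs(b)) + 1e-12))


def equivariance_battery(
    model: ScoreModel, n_trials: int = 100, seed: int = 0, n_atoms: int = 4
) -> dict[str, float]:
    """Max relative errors of the symmetry contracts over random
    (rotation-or-reflection, permutation) pairs.

    Contract: score_X and score_A transform by the permutation alone
    (invariance to the orthogonal action on P), score_P additionally
    rotates with R.
    """
    rng = np.random.default_rng(seed)
    errs = {"x_invariance": 0.0, "p_equivariance": 0.0, "a_invariance": 0.0}
    for _ in range(n_trials):
        state = random_state(rng, n_atoms=n_atoms, k=model.k,
                             t=float(rng.uniform(0.05, 1.0)))
        base = model(state)
        R = random_orthogonal(rng)
        perm = rng.permutation(n_atoms)
        moved = model(_transform_state(state, R, perm))
        errs["x_invariance"] = max(errs["x_invariance"],
                                   _rel_err(moved.X, base.X[:, perm, :]))
        errs["p_equivariance"] = max(errs["p_equivariance"],
                                     _rel_err(moved.P, base.P[:, perm, :] @ R))
        errs["a_invariance"] = max(errs["a_invariance"],
                                   _rel_err(moved.A, base.A[:, perm][:, :, perm]))
    return errs


def conditional_score_vs_numerical(
    n_points: int = 50, seed: int = 0, h: float = 1e-4
) -> float:
    """Max |analytic - central-difference| over random entries of all three
    component scores of the Gaussian transition log-density."""
    rng = np.random.default_rng(seed)
    fixtures = make_fixtures(FixtureSpec(count_per_template=1, jitter_std=0.05,
                                         seed=seed))
    batch = MoleculeBatch.from_molecules(fixtures)
    spec = DiffusionSpec()
    worst = 0.0
    for _ in range(n_points):
        t = float(rng.uniform(0.05, 1.0))
        state = perturb(batch, t, spec, rng)
        target = conditional_score_target(batch, state, spec)
        b = int(rng.integers(0, batch.n_molecules))
        n = int(batch.mask[b].sum())

        # X entry: d/dx of -(x - alpha x0)^2 / (2 sigma^2) by central difference
        ax, sx = spec.schedule_x.alpha_sigma(t)
        i, c = int(rng.integers(0, n)), int(rng.integers(0, batch.X.shape[2]))
        vx, v0 = state.X[b, i, c], batch.X[b, i, c]
        fd = (
            (-0.5 * ((vx + h) - ax * v0) ** 2 / sx**2)
            - (-0.5 * ((vx - h) - ax * v0) ** 2 / sx**2)
        ) / (2 * h)
        worst = max(worst, abs(fd - target.X[b, i, c]))

        # A upper-triangle entry: independent Gaussian per unordered pair
        aa, sa = spec.schedule_a.alpha_sigma(t)
        if n >= 2:
            i, j = sorted(rng.choice(n, size=2, replace=False))
            va, v0 = state.A[b, i, j], batch.A[b, i, j]
            num = -((va - aa * v0) / sa**2)
            fd = (
                (-0.5 * ((va + h) - aa * v0) ** 2 / sa**2)
                - (-0.5 * ((va - h) - aa * v0) ** 2 / sa**2)
            ) / (2 * h)
            worst = max(worst, abs(fd - num), abs(fd - target.A[b, i, j]))

        # P: finite-difference gradient of the ambient Gaussian, projected
        ap, sp = spec.schedule_p.alpha_sigma(t)
        grad = -(state.P[b, :n] - ap * batch.P[b, :n]) / sp**2
        grad_fd = np.zeros_like(grad)
        for ii in range(n):
            for cc in range(3):
                pp, pm = state.P[b, :n].copy(), state.P[b, :n].copy()
                pp[ii, cc] += h
                pm[ii, cc] -= h
                grad_fd[ii, cc] = (
                    -0.5 * np.sum((pp - ap * batch.P[b, :n]) ** 2) / sp**2
                    + 0.5 * np.sum((pm - ap * batch.P[b, :n]) ** 2) / sp**2
                ) / (2 * h)
        proj = grad_fd - grad_fd.mean(axis=0, keepdims=True)
        worst = max(worst, float(np.max(np.abs(proj - target.P[b, :n]))))
    return worst


def forward_convergence_moments(
    n_draws: int = 10_000, seed: int = 0, jitter_std: float = 0.02
) -> dict[str, float]:
    """Moments of M_T over repeated perturbations of fixture molecules,
    compared with the prior (unit variance; (N-1)/N per axis for P)."""
    rng = np.random.default_rng(seed)
    fixtures = make_fixtures(
        FixtureSpec(count_per_template=25, jitter_std=jitter_std, seed=seed)
    )
    batch = MoleculeBatch.from_molecules(fixtures)
    spec = DiffusionSpec()
    xs, ps, as_, p_expected = [], [], [], []
    reps = max(1, n_draws // batch.n_molecules)
    for _ in range(reps):
        state = perturb(batch, spec.T, spec, rng)
        node = batch.mask.astype(bool)
        pair = state.pair_mask().astype(bool)
        xs.append(state.X[node].ravel())
        ps.append(state.P[node].ravel())
        as_.append(state.A[pair].ravel())
        n_per = batch.mask.sum(axis=1)
        p_expected.append(np.repeat((n_per - 1) / n_per, (n_per * 3).astype(int)))
    x, p, a = np.concatenate(xs), np.concatenate(ps), np.concatenate(as_)
    return {
        "x_mean_abs": float(abs(x.mean())),
        "p_mean_abs": float(abs(p.mean())),
        "a_mean_abs": float(abs(a.mean())),
        "x_var_dev": float(abs(x.var() - 1.0)),
        "p_var_dev": float(abs(p.var() - np.concatenate(p_expected).mean())),
        "a_var_dev": float(abs(a.var() - 1.0)),
    }


def solver_gaussian_moments(
    n_samples: int = 5000,
    n_steps: int = 200,
    target_var: float = 0.25,
    seed: int = 0,
    corrector_steps: int = 1,
    snr: float = 0.16,
) -> tuple[float, float]:
    """PC-sample a 1-D Gaussian N(0, target_var) with the ANALYTIC score.

    The state is a single-atom, single-feature molecule: P and A are
    degenerate (zero) so the check isolates the solver on the X channel
    while exercising the full molecular code path.
    """
    spec = DiffusionSpec()

    def analytic_score(state: NoisedState) -> PartialScores:
        alpha, sigma = spec.schedule_x.alpha_sigma(state.t)
        var = alpha**2 * target_var + sigma**2
        return PartialScores(
            X=-state.X / var[:, None, None],
            P=np.zeros_like(state.P),
            A=np.zeros_like(state.A),
        )

    cfg = SamplerConfig(n_steps=n_steps, corrector_steps=corrector_steps,
                        snr=snr, seed=seed)
    state, _ = pc_sample(analytic_score, n_atoms=1, config=cfg, spec=spec,
                         k=1, n_samples=n_samples)
    x = state.X.ravel()
    return float(x.mean()), float(x.var())


def run_selftest(seed: int = 0) -> list[tuple[str, str]]:
    """Trimmed oracle suite for the CLI; returns a list of failures."""
    failures: list[tuple[str, str]] = []
    model = ScoreModel(NetworkConfig(l_h=2, l_r=2, l_a=2, k_power=2, heads=2,
                                     hidden=32), k=DEFAULT_VOCABULARY.k, seed=seed)
    errs = equivariance_battery(model, n_trials=20, seed=seed)
    for name, err in errs.items():
        if err > 1e-5:
            failures.append((f"equivariance.{name}", f"relative error {err:.2e}"))
    worst = conditional_score_vs_numerical(n_points=10, seed=seed)
    if worst > 1e-6:
        failures.append(("conditional_score", f"max deviation {worst:.2e}"))
    mean, var = solver_gaussian_moments(n_samples=1000, n_steps=100, seed=seed)
    if abs(mean) > 0.1 or abs(var - 0.25) > 0.1:
        failures.append(("solver", f"mean {mean:.3f}, var {var:.3f}"))
    return failures
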