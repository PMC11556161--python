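"""Forward diffusion: per-component VP-SDEs over (X, P, A).

The joint state of a molecule is noised by three independent
variance-preserving SDEs, one per component of the feature space:

    du = -1/2 beta(t) u dt + sqrt(beta(t)) dw,   t in [0, T]

whose transition kernel is the closed-form Gaussian
``u_t ~ N(alpha_t u_0, sigma_t^2 I)`` with
``alpha_t = exp(-1/2 int_0^t beta(s) ds)`` and ``sigma_t^2 = 1 - alpha_t^2``.
beta(t) rises linearly from ``beta_min`` to ``beta_max``.

Component-specific conventions keep each trajectory inside its admissible
subspace: coordinate noise is mean-subtracted per axis, so P_t stays in the
zero-center-of-mass subspace, and adjacency noise is sampled on the strict
upper triangle, mirrored, with a zero diagonal, so A_t stays symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mol_data import MoleculeBatch

__all__ = [
    "NoiseSchedule",
    "DiffusionSpec",
    "NoisedState",
    "PartialScores",
    "vp_coefficients",
    "drift_diffusion",
    "perturb",
    "conditional_score_target",
    "sample_prior",
    "symmetrize_offdiag",
    "project_p_noise",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Variance-preserving schedule with beta(t) linear in t."""

    kind: str = "VP"
    beta_min: float = 0.1
    beta_max: float = 20.0
    T: float = 1.0

    def __post_init__(self):
        if self.kind != "VP":
            raise ValueError(f"unsupported schedule kind {self.kind!r}")
        if not (0 < self.beta_min <= self.beta_max):
            raise ValueError("need 0 < beta_min <= beta_max")
        if self.T <= 0:
            raise ValueError("time horizon T must be positive")

    def beta(self, t):
        t = np.asarray(t, dtype=np.float64)
        return self.beta_min + (self.beta_max - self.beta_min) * t / self.T

    def beta_integral(self, t):
        t = np.asarray(t, dtype=np.float64)
        return self.beta_min * t + 0.5 * (self.beta_max - self.beta_min) * t**2 / self.T

    def alpha_sigma(self, t):
        t = np.asarray(t, dtype=np.float64)
        if np.any(t < 0) or np.any(t > self.T + 1e-12):
            raise ValueError(f"t must lie in [0, {self.T}]")
        alpha = np.exp(-0.5 * self.beta_integral(t))
        sigma = np.sqrt(np.clip(1.0 - alpha**2, 0.0, 1.0))
        return alpha, sigma


def vp_coefficients(t, schedule: NoiseSchedule):
    """(alpha_t, sigma_t) of the VP transition kernel at time t."""
    return schedule.alpha_sigma(t)


def drift_diffusion(t, u, schedule: NoiseSchedule):
    """Forward-SDE drift f(u) = -1/2 beta(t) u (linear) and scalar diffusion g."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0) or np.any(t > schedule.T + 1e-12):
        raise ValueError(f"t must lie in [0, {schedule.T}]")
    beta = schedule.beta(t)
    return -0.5 * beta * np.asarray(u, dtype=np.float64), np.sqrt(beta)


@dataclass(frozen=True)
class DiffusionSpec:
    """Independent per-component schedules sharing one time horizon T."""

    schedule_x: NoiseSchedule = field(default_factory=NoiseSchedule)
    schedule_p: NoiseSchedule = field(default_factory=NoiseSchedule)
    schedule_a: NoiseSchedule = field(default_factory=NoiseSchedule)

    def __post_init__(self):
        horizons = {self.schedule_x.T, self.schedule_p.T, self.schedule_a.T}
        if len(horizons) != 1:
            raise ValueError("all component schedules must share the same T")

    @property
    def T(self) -> float:
        return self.schedule_x.T


@dataclass
class NoisedState:
    """Batched noised molecular state (X_t, P_t, A_t) at time(s) t with node mask."""

    X: np.ndarray  # (B, N, k)
    P: np.ndarray  # (B, N, 3)
    A: np.ndarray  # (B, N, N)
    t: np.ndarray  # (B,)
    mask: np.ndarray  # (B, N)

    def __post_init__(self):
        self.t = np.broadcast_to(
            np.asarray(self.t, dtype=np.float64), (self.X.shape[0],)
        ).copy()

    @property
    def n_molecules(self) -> int:
        return self.X.shape[0]

    def pair_mask(self) -> np.ndarray:
        """(B, N, N) mask of real off-diagonal pairs."""
        m = self.mask[:, :, None] * self.mask[:, None, :]
        eye = np.eye(self.mask.shape[1])[None]
        return m * (1.0 - eye)

    def copy(self) -> "NoisedState":
        return NoisedState(
            self.X.copy(), self.P.copy(), self.A.copy(), self.t.copy(), self.mask.copy()
        )


@dataclass
class PartialScores:
    """Estimated (or target) gradients of log p_t w.r.t. each component."""

    X: np.ndarray  # (B, N, k)
    P: np.ndarray  # (B, N, 3)
    A: np.ndarray  # (B, N, N), symmetric, zero diagonal


def symmetrize_offdiag(eps: np.ndarray) -> np.ndarray:
    """Mirror the strict upper triangle onto the lower; zero the diagonal.

    Keeps per-entry variance at 1 when `eps` is iid standard normal (the
    lower triangle is a copy, not an average).
    """
    n = eps.shape[-1]
    upper = np.triu(eps, k=1)
    return upper + np.swapaxes(upper, -1, -2)


def project_p_noise(eps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Subtract the masked per-axis mean so coordinate noise has zero CoM."""
    m = mask[..., None]
    counts = np.maximum(m.sum(axis=-2, keepdims=True), 1.0)
    mean = (eps * m).sum(axis=-2, keepdims=True) / counts
    return (eps - mean) * m


def _coeffs(schedule: NoiseSchedule, t: np.ndarray, extra_dims: int):
    alpha, sigma = schedule.alpha_sigma(t)
    shape = t.shape + (1,) * extra_dims
    return alpha.reshape(shape), sigma.reshape(shape)


def perturb(
    batch: MoleculeBatch, t, spec: DiffusionSpec, rng: np.random.Generator
) -> NoisedState:
    """Draw M_t ~ p_0t(M_t | M_0) from the closed-form VP transition kernel.

    ``t`` may be a scalar or a per-molecule vector; t=0 entries reproduce
    M_0 exactly (degenerate kernel).
    """
    b, n = batch.mask.shape
    t = np.broadcast_to(np.asarray(t, dtype=np.float64), (b,)).copy()

    ax, sx = _coeffs(spec.schedule_x, t, 2)
    ap, sp = _coeffs(spec.schedule_p, t, 2)
    aa, sa = _coeffs(spec.schedule_a, t, 2)

    node = batch.mask[:, :, None]
    eps_x = rng.standard_normal(batch.X.shape) * node
    eps_p = project_p_noise(rng.standard_normal(batch.P.shape), batch.mask)
    pair = batch.mask[:, :, None] * batch.mask[:, None, :] * (1.0 - np.eye(n)[None])
    eps_a = symmetrize_offdiag(rng.standard_normal(batch.A.shape)) * pair

    return NoisedState(
        X=ax * batch.X + sx * eps_x,
        P=ap * batch.P + sp * eps_p,
        A=aa * batch.A + sa * eps_a,
        t=t,
        mask=batch.mask.copy(),
    )


def conditional_score_target(
    batch: MoleculeBatch, state: NoisedState, spec: DiffusionSpec
) -> PartialScores:
    """Gradient of the Gaussian transition log-density at M_t given M_0.

    For each component, ``grad log N(u_t; alpha_t u_0, sigma_t^2 I) =
    -(u_t - alpha_t u_0) / sigma_t^2``.  Undefined at t=0 (sigma=0).
    """
    t = state.t
    if np.any(t <= 0):
        raise ValueError("conditional score is undefined at t=0 (sigma_t=0)")
    ax, sx = _coeffs(spec.schedule_x, t, 2)
    ap, sp = _coeffs(spec.schedule_p, t, 2)
    aa, sa = _coeffs(spec.schedule_a, t, 2)

    node = batch.mask[:, :, None]
    score_x = -(state.X - ax * batch.X) / sx**2 * node
    score_p = project_p_noise(-(state.P - ap * batch.P) / sp**2, batch.mask)
    score_a = -(state.A - aa * batch.A) / sa**2 * state.pair_mask()
    return PartialScores(X=score_x, P=score_p, A=score_a)


def sample_prior(
    n_atoms: int,
    k: int,
    spec: DiffusionSpec,
    rng: np.random.Generator,
    n_samples: int = 1,
    mask: np.ndarray | None = None,
) -> NoisedState:
    """Draw the t=T prior: standard normal X and A (symmetric, zero diagonal),
    standard normal P projected to the zero-CoM subspace."""
    if n_atoms < 1:
        raise ValueError("need at least one atom")
    if mask is None:
        mask = np.ones((n_samples, n_atoms))
    b, n = mask.shape
    node = mask[:, :, None]
    pair = mask[:, :, None] * mask[:, None, :] * (1.0 - np.eye(n)[None])
    X = rng.standard_normal((b, n, k)) * node
    P = project_p_noise(rng.standard_normal((b, n, 3)), mask)
    A = symmetrize_offdiag(rng.standard_normal((b, n, n))) * pair
    return NoisedState(X=X, P=P, A=A, t=np.full(b, spec.T), mask=mask.copy())
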