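"""Reverse-time generation: Predictor-Corrector solver and decoding.

The predictor is a reverse-time Euler-Maruyama step of the per-component
SDE  du = [f(u) - g^2 s(u, t)] dt + g dw~  (dt < 0); the corrector is
Langevin MCMC at fixed t with the signal-to-noise step size
eta = 2 (r ||xi|| / ||s||)^2.  Component conventions are preserved at every
step: coordinate noise and updates stay on the zero-CoM subspace and
adjacency noise stays symmetric with a zero diagonal.

The last move replaces a noise-adding step with the conditional-mean
(Tweedie) denoising at t_min, u_0 ~= (u + sigma^2 s) / alpha, which removes
residual noise without altering the SDE contract.  Decoding maps the final
continuous state to a discrete molecule: row-argmax atom types (ties break
to the lowest vocabulary index), adjacency symmetrized, clipped to [0, 3]
and rounded half-up, coordinates re-centered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mol_data import Molecule, sample_atom_count, project_to_zero_com
from .sde import (
    DiffusionSpec,
    NoisedState,
    NoiseSchedule,
    PartialScores,
    project_p_noise,
    sample_prior,
    symmetrize_offdiag,
)
from .vocab import DEFAULT_VOCABULARY, AtomVocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "GenerationResult",
    "predictor_step",
    "corrector_step",
    "pc_sample",
    "decode",
    "generate",
]


@dataclass(frozen=True)
class SamplerConfig:
    n_steps: int = 1000
    corrector_steps: int = 1  # Langevin steps per predictor step (M)
    snr: float = 0.16  # corrector signal-to-noise ratio (r)
    t_min: float = 1e-3
    grid: str = "uniform"  # "quadratic" spends more steps at low noise
    final_corrector_steps: int = 0  # extra Langevin polish at t_min
    clip_value: float = 100.0  # numerical guard; legitimate states stay within +-5
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.corrector_steps < 0:
            raise ValueError("corrector_steps must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.clip_value <= 0:
            raise ValueError("clip_value must be > 0")
        if self.grid not in ("uniform", "quadratic"):
            raise ValueError("grid must be 'uniform' or 'quadratic'")
        if self.final_corrector_steps < 0:
            raise ValueError("final_corrector_steps must be >= 0")

    def time_grid(self, T: float) -> np.ndarray:
        if self.grid == "uniform":
            return np.linspace(T, self.t_min, self.n_steps + 1)
        ramp = np.linspace(1.0, 0.0, self.n_steps + 1) ** 2
        return self.t_min + (T - self.t_min) * ramp


@dataclass
class GenerationResult:
    molecules: list[Molecule]
    com_drift_max: float = 0.0
    final_t: float = 0.0
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-component updates (shared by the molecular and the scalar/1-D paths)
# ---------------------------------------------------------------------------


def _em_update(u, t, dt, score, schedule: NoiseSchedule, noise):
    """One reverse Euler-Maruyama move of du = [f - g^2 s] dt + g dw~."""
    beta = schedule.beta(t)
    drift = -0.5 * beta * u - beta * score
    return u + drift * dt + np.sqrt(beta) * np.sqrt(-dt) * noise


def _langevin_update(u, score, noise, snr, axes):
    """Langevin step, eta = 2 (r ||xi|| / ||s||)^2 per component.

    Norms are per-sample norms averaged over the batch (the standard PC
    scaling), which keeps the step size finite when an individual chain
    passes near a score zero; an identically-zero score skips the update.
    """
    score_norm = np.sqrt((score**2).sum(axis=axes)).mean()
    noise_norm = np.sqrt((noise**2).sum(axis=axes)).mean()
    if score_norm == 0.0:
        _warn_zero_score()
        return u
    eta = 2.0 * (snr * noise_norm / score_norm) ** 2
    return u + eta * score + np.sqrt(2.0 * eta) * noise


_zero_score_warned = False


def _warn_zero_score():
    global _zero_score_warned
    if not _zero_score_warned:
        logger.warning("corrector: zero score norm encountered, update skipped")
        _zero_score_warned = True


def _draw_noises(state: NoisedState, rng: np.random.Generator):
    node = state.mask[..., None]
    eps_x = rng.standard_normal(state.X.shape) * node
    eps_p = project_p_noise(rng.standard_normal(state.P.shape), state.mask)
    eps_a = symmetrize_offdiag(rng.standard_normal(state.A.shape)) * state.pair_mask()
    return eps_x, eps_p, eps_a


def predictor_step(
    state: NoisedState,
    dt: float,
    scores: PartialScores,
    spec: DiffusionSpec,
    rng: np.random.Generator,
) -> NoisedState:
    """Reverse Euler-Maruyama over all three components (dt < 0)."""
    if dt >= 0:
        raise ValueError("predictor integrates reverse time: dt must be negative")
    t = state.t
    eps_x, eps_p, eps_a = _draw_noises(state, rng)
    tc = t[:, None, None]
    X = _em_update(state.X, tc, dt, scores.X, spec.schedule_x, eps_x)
    P = _em_update(state.P, tc, dt, scores.P, spec.schedule_p, eps_p)
    A = _em_update(state.A, tc, dt, scores.A, spec.schedule_a, eps_a)
    X *= state.mask[..., None]
    P = project_p_noise(P, state.mask)
    A *= state.pair_mask()
    for name, arr in (("X", X), ("P", P), ("A", A)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                f"non-finite predictor update of {name} at t={t.mean():.4f}"
            )
    return NoisedState(X=X, P=P, A=A, t=t + dt, mask=state.mask.copy())


def corrector_step(
    state: NoisedState,
    scores: PartialScores,
    snr: float,
    spec: DiffusionSpec,
    rng: np.random.Generator,
) -> NoisedState:
    """One Langevin MCMC correction at fixed t, per component."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    eps_x, eps_p, eps_a = _draw_noises(state, rng)
    X = _langevin_update(state.X, scores.X * state.mask[..., None], eps_x, snr, (1, 2))
    P = _langevin_update(state.P, scores.P, eps_p, snr, (1, 2))
    A = _langevin_update(state.A, scores.A * state.pair_mask(), eps_a, snr, (1, 2))
    X *= state.mask[..., None]
    P = project_p_noise(P, state.mask)
    A *= state.pair_mask()
    return NoisedState(X=X, P=P, A=A, t=state.t.copy(), mask=state.mask.copy())


_clip_warned = False


def _clamp_state(state: NoisedState, bound: float) -> NoisedState:
    """Magnitude guard: an untrained or diverging score can push the state
    far outside the data range; clipping keeps the pipeline total without
    affecting converged runs (whose values stay within a few units)."""
    global _clip_warned
    if max(np.abs(state.X).max(), np.abs(state.P).max(), np.abs(state.A).max()) <= bound:
        return state
    if not _clip_warned:
        logger.warning("sampler state exceeded +-%g, clipping (diverging model?)",
                       bound)
        _clip_warned = True
    state.X = np.clip(state.X, -bound, bound)
    state.A = np.clip(state.A, -bound, bound)
    state.P = project_p_noise(np.clip(state.P, -bound, bound), state.mask)
    return state


def _com_drift(state: NoisedState) -> float:
    counts = np.maximum(state.mask.sum(axis=1), 1.0)[:, None]
    coms = np.abs((state.P * state.mask[..., None]).sum(axis=1)) / counts
    return float(coms.max())


def pc_sample(
    score_fn,
    n_atoms: int,
    config: SamplerConfig,
    spec: DiffusionSpec,
    k: int | None = None,
    n_samples: int = 1,
    vocab: AtomVocabulary = DEFAULT_VOCABULARY,
    rng: np.random.Generator | None = None,
) -> tuple[NoisedState, dict]:
    """Integrate the reverse-time SDEs from the prior down to t_min.

    ``score_fn`` maps a :class:`NoisedState` to :class:`PartialScores`
    (a trained :class:`~molsde.nets.ScoreModel` or an analytic oracle).
    Returns the state at ``t_min`` after a final conditional-mean
    (Tweedie) denoising move, plus trajectory diagnostics.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if k is None:
        k = vocab.k
    state = sample_prior(n_atoms, k, spec, rng, n_samples=n_samples)
    grid = config.time_grid(spec.T)
    drift_max = _com_drift(state)
    for i in range(config.n_steps):
        dt = float(grid[i + 1] - grid[i])
        state = _clamp_state(
            predictor_step(state, dt, score_fn(state), spec, rng), config.clip_value
        )
        for _ in range(config.corrector_steps):
            state = _clamp_state(
                corrector_step(state, score_fn(state), config.snr, spec, rng),
                config.clip_value,
            )
        drift_max = max(drift_max, _com_drift(state))
    for _ in range(config.final_corrector_steps):
        state = _clamp_state(
            corrector_step(state, score_fn(state), config.snr, spec, rng),
            config.clip_value,
        )
        drift_max = max(drift_max, _com_drift(state))
    # conditional-mean denoising at t_min: u0 ~ (u + sigma^2 s) / alpha
    scores = score_fn(state)
    tc = state.t[:, None, None]
    out = state.copy()
    for name, schedule, s in (
        ("X", spec.schedule_x, scores.X),
        ("P", spec.schedule_p, scores.P),
        ("A", spec.schedule_a, scores.A),
    ):
        alpha, sigma = schedule.alpha_sigma(tc)
        u = getattr(state, name)
        setattr(out, name, (u + sigma**2 * s) / alpha)
    out.X *= out.mask[..., None]
    out.P = project_p_noise(out.P, out.mask)
    out.A *= out.pair_mask()
    out = _clamp_state(out, config.clip_value)
    drift_max = max(drift_max, _com_drift(out))
    diagnostics = {"com_drift_max": drift_max, "final_t": float(state.t.mean())}
    return out, diagnostics


def decode(
    state: NoisedState, vocab: AtomVocabulary = DEFAULT_VOCABULARY
) -> list[Molecule]:
    """Discretize a continuous state into molecules (one per batch row).

    Atom types by row-argmax (ties resolved to the lowest vocabulary index);
    adjacency symmetrized, clipped to [0, 3], rounded half-up; coordinates
    re-centered.
    """
    out = []
    for b in range(state.n_molecules):
        n = int(state.mask[b].sum())
        X = state.X[b, :n]
        onehot = np.zeros((n, vocab.k))
        onehot[np.arange(n), X.argmax(axis=1)] = 1.0
        A = 0.5 * (state.A[b, :n, :n] + state.A[b, :n, :n].T)
        A = np.floor(np.clip(A, 0.0, 3.0) + 0.5)
        np.fill_diagonal(A, 0.0)
        P = project_to_zero_com(state.P[b, :n])
        out.append(Molecule(X=onehot, P=P, A=A, vocab=vocab))
    return out


def generate(
    model,
    dataset,
    config: SamplerConfig,
    spec: DiffusionSpec,
    n_samples: int,
    vocab: AtomVocabulary = DEFAULT_VOCABULARY,
) -> GenerationResult:
    """Sample ``n_samples`` molecules, drawing atom counts from the dataset's
    empirical size distribution and batching same-size molecules together."""
    rng = np.random.default_rng(config.seed)
    sizes = [sample_atom_count(dataset, rng) for _ in range(n_samples)]
    by_size: dict[int, list[int]] = {}
    for i, n in enumerate(sizes):
        by_size.setdefault(n, []).append(i)
    molecules: list[Molecule | None] = [None] * n_samples
    drift_max, final_t = 0.0, config.t_min
    for n, indices in sorted(by_size.items()):
        state, diag = pc_sample(
            model, n, config, spec, k=vocab.k, n_samples=len(indices),
            vocab=vocab, rng=rng,
        )
        drift_max = max(drift_max, diag["com_drift_max"])
        final_t = diag["final_t"]
        for slot, mol in zip(indices, decode(state, vocab)):
            molecules[slot] = mol
    return GenerationResult(
        molecules=list(molecules),  # type: ignore[arg-type]
        com_drift_max=drift_max,
        final_t=final_t,
        diagnostics={"sizes": sizes},
    )
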