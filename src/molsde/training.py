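"""Denoising score matching: losses and the optimization loop.

Each partial-score network is trained to regress the conditional
(transition-kernel) score, the tractable stand-in for the intractable
marginal score:

    L_c = E_t gamma_c(t) E_{M_0} E_{M_t | M_0}
          || s_c(M_t, t) - grad_c log p_0t(c_t | c_0) ||^2

Monte-Carlo estimated per step over a molecule batch with one uniform
t ~ U[t_min, T] per molecule.  The default weighting gamma_c(t) =
sigma_{c,t}^2 turns the regression into bounded noise prediction
(sigma * target = -epsilon).  The three minimizations are independent;
one shared optimizer steps their disjoint parameter sets jointly, which
is equivalent to stepping them separately.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, tensor
from .mol_data import Molecule, MoleculeBatch
from .nets import ScoreModel
from .nn import EMA, Adam
from .sde import DiffusionSpec, conditional_score_target, perturb

__all__ = ["TrainConfig", "LossBreakdown", "dsm_losses", "train", "TrainResult"]

_GAMMA_MODES = ("sigma_sq", "g_sq", "uniform")


@dataclass(frozen=True)
class TrainConfig:
    steps: int = 1500
    batch_size: int = 64
    lr: float = 2e-3
    lr_schedule: str = "cosine"  # "cosine" decays to lr_final_fraction * lr
    lr_final_fraction: float = 0.05
    t_min: float = 1e-5
    gamma: str = "sigma_sq"
    ema_decay: float = 0.999
    clip_norm: float = 1.0
    bucket_by_size: bool = True  # one molecule size per step (no padding waste)
    bucket_size_power: float = 0.0  # bucket prob ~ count * n_atoms^power
    t_low_fraction: float = 0.0  # fraction of t draws from [t_min, t_low_cap]
    t_low_cap: float = 0.25  # low-noise emphasis region (geometry precision)
    seed: int = 0
    log_every: int = 10

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if not 0 < self.t_min < 1:
            raise ValueError("t_min must be in (0, T)")
        if not 0 <= self.ema_decay < 1:
            raise ValueError("EMA decay must be in [0, 1)")
        if self.gamma not in _GAMMA_MODES:
            raise ValueError(f"gamma must be one of {_GAMMA_MODES}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")
        if not 0.0 <= self.t_low_fraction <= 1.0:
            raise ValueError("t_low_fraction must be in [0, 1]")
        if not self.t_min < self.t_low_cap <= 1.0:
            raise ValueError("t_low_cap must be in (t_min, T]")

    def lr_at(self, step: int) -> float:
        """Learning rate at 1-based step (cosine decay or constant)."""
        if self.lr_schedule == "constant" or self.steps == 1:
            return self.lr
        frac = (step - 1) / (self.steps - 1)
        floor = self.lr_final_fraction
        return self.lr * (floor + (1 - floor) * 0.5 * (1 + np.cos(np.pi * frac)))


@dataclass
class LossBreakdown:
    loss_x: float
    loss_p: float
    loss_a: float

    @property
    def total(self) -> float:
        return self.loss_x + self.loss_p + self.loss_a

    def __post_init__(self):
        for name in ("loss_x", "loss_p", "loss_a"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise FloatingPointError(f"{name} is not finite ({v})")


def _gamma(mode: str, schedule, t: np.ndarray) -> np.ndarray:
    if mode == "sigma_sq":
        _, sigma = schedule.alpha_sigma(t)
        return sigma**2
    if mode == "g_sq":
        return schedule.beta(t)
    return np.ones_like(t)


def _component_loss(score: Tensor, target: np.ndarray, mask: np.ndarray,
                    gamma: np.ndarray, name: str) -> Tensor:
    """gamma(t)-weighted squared error, summed per molecule, averaged over batch."""
    diff = (score - tensor(target)) * mask
    axes = tuple(range(1, diff.ndim))
    per_mol = (diff * diff).sum(axis=axes)
    loss = (per_mol * gamma).mean()
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"non-finite {name} loss")
    return loss


def dsm_loss_tensors(
    model: ScoreModel,
    batch: MoleculeBatch,
    t: np.ndarray,
    spec: DiffusionSpec,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[Tensor, Tensor, Tensor]:
    """Taped per-component DSM losses for one Monte-Carlo batch."""
    state = perturb(batch, t, spec, rng)
    target = conditional_score_target(batch, state, spec)
    sx, sp, sa = model.forward(state)
    node = batch.mask[..., None]
    pair = state.pair_mask()
    lx = _component_loss(sx, target.X, node, _gamma(config.gamma, spec.schedule_x, t), "X")
    lp = _component_loss(sp, target.P, node, _gamma(config.gamma, spec.schedule_p, t), "P")
    la = _component_loss(sa, target.A, pair, _gamma(config.gamma, spec.schedule_a, t), "A")
    return lx, lp, la


def dsm_losses(
    model: ScoreModel,
    batch: MoleculeBatch,
    t: np.ndarray,
    spec: DiffusionSpec,
    config: TrainConfig,
    rng: np.random.Generator,
) -> LossBreakdown:
    """Monte-Carlo DSM loss breakdown (no gradient tape retained by caller)."""
    lx, lp, la = dsm_loss_tensors(model, batch, t, spec, config, rng)
    return LossBreakdown(float(lx.data), float(lp.data), float(la.data))


@dataclass
class TrainResult:
    model: ScoreModel
    ema: EMA
    history: list[dict] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.history[-1]["total"] if self.history else float("nan")


def train(
    dataset: Sequence[Molecule],
    model: ScoreModel,
    spec: DiffusionSpec,
    config: TrainConfig,
    metrics_path: str | Path | None = None,
) -> TrainResult:
    """Optimize the three score networks by denoising score matching.

    Deterministic under a fixed ``config.seed`` on one device.  EMA shadow
    weights are maintained throughout and are the ones meant for sampling.
    Aborts if the total loss exceeds 1e6 (divergence).
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.lr, clip_norm=config.clip_norm)
    ema = EMA(model, decay=config.ema_decay)
    T = spec.T
    history: list[dict] = []

    # size buckets: drawing one molecule size per step avoids padding waste
    # while keeping the per-molecule sampling distribution uniform
    buckets: list[np.ndarray] = []
    bucket_probs: np.ndarray | None = None
    if config.bucket_by_size:
        by_size: dict[int, list[int]] = {}
        for i, m in enumerate(dataset):
            by_size.setdefault(m.n_atoms, []).append(i)
        buckets = [np.array(v) for v in by_size.values()]
        # optional size weighting: larger molecules are harder conditional
        # targets, so they may receive proportionally more steps
        weights = np.array([
            len(v) * n**config.bucket_size_power for n, v in by_size.items()
        ])
        bucket_probs = weights / weights.sum()

    for step in range(1, config.steps + 1):
        if config.bucket_by_size:
            bucket = buckets[rng.choice(len(buckets), p=bucket_probs)]
            idx = bucket[rng.integers(0, len(bucket), size=config.batch_size)]
        else:
            idx = rng.integers(0, len(dataset), size=config.batch_size)
        batch = MoleculeBatch.from_molecules([dataset[i] for i in idx])
        t = rng.uniform(config.t_min, T, size=config.batch_size)
        if config.t_low_fraction > 0:
            # oversample low noise levels, where geometric precision is learned
            low = rng.random(config.batch_size) < config.t_low_fraction
            t[low] = rng.uniform(config.t_min, config.t_low_cap, size=low.sum())
        model.zero_grad()
        lx, lp, la = dsm_loss_tensors(model, batch, t, spec, config, rng)
        total = lx + lp + la
        if float(total.data) > 1e6:
            raise RuntimeError(
                f"training diverged at step {step}: total loss {float(total.data):.3e}"
            )
        total.backward()
        optimizer.lr = config.lr_at(step)
        optimizer.step()
        ema.update()
        if step == 1 or step % config.log_every == 0 or step == config.steps:
            history.append(
                {
                    "step": step,
                    "loss_x": float(lx.data),
                    "loss_p": float(lp.data),
                    "loss_a": float(la.data),
                    "total": float(total.data),
                }
            )

    if metrics_path is not None:
        with open(metrics_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["step", "loss_x", "loss_p", "loss_a", "total"]
            )
            writer.writeheader()
            writer.writerows(history)
    return TrainResult(model=model, ema=ema, history=history)
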