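"""Denoising-score-matching losses and the optimization loop."""

import numpy as np
import pytest

from molsde.mol_data import FixtureSpec, MoleculeBatch, make_fixtures
from molsde.nets import NetworkConfig, ScoreModel
from molsde.nn import EMA
from molsde.sde import (
    DiffusionSpec,
    conditional_score_target,
    perturb,
)
from molsde.selftest import random_orthogonal
from molsde.training import TrainConfig, dsm_losses, train


class _OracleModel:
    """Debug score model returning the exact conditional target."""

    def __init__(self, batch, spec):
        self.batch = batch
        self.spec = spec

    def forward(self, state):
        from molsde.autodiff import Tensor

        t = conditional_score_target(self.batch, state, self.spec)
        return Tensor(t.X), Tensor(t.P), Tensor(t.A)


class _ZeroModel:
    def forward(self, state):
        from molsde.autodiff import Tensor

        return (Tensor(np.zeros_like(state.X)), Tensor(np.zeros_like(state.P)),
                Tensor(np.zeros_like(state.A)))


class TestDSMLosses:
    def test_oracle_net_gives_zero_loss(self, fixture_batch, spec, rng):
        cfg = TrainConfig(seed=0)
        t = rng.uniform(0.1, 1.0, fixture_batch.n_molecules)
        losses = dsm_losses(_OracleModel(fixture_batch, spec), fixture_batch, t,
                            spec, cfg, rng)
        assert losses.total == pytest.approx(0.0, abs=1e-20)

    def test_zero_net_sigma_sq_loss_counts_unmasked_entries(self, spec):
        # with gamma = sigma^2 the X target is -eps/sigma, so the per-molecule
        # loss of a zero net is E||eps||^2 = number of unmasked X entries
        mols = make_fixtures(FixtureSpec(templates=("methane",),
                                         count_per_template=64, jitter_std=0.02,
                                         seed=1))
        batch = MoleculeBatch.from_molecules(mols)
        cfg = TrainConfig(seed=0)
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(30):
            t = rng.uniform(0.1, 1.0, batch.n_molecules)
            vals.append(dsm_losses(_ZeroModel(), batch, t, spec, cfg, rng).loss_x)
        n_entries = 5 * 5  # methane: N=5 atoms, k=5 one-hot columns
        n_draws = 30 * 64
        se = np.sqrt(2.0 * n_entries / n_draws)  # var of chi^2_k is 2k
        assert abs(np.mean(vals) - n_entries) < 3 * se

    def test_losses_nonnegative_for_random_models(self, fixture_batch, spec):
        cfg = TrainConfig(seed=0)
        for seed in range(5):
            model = ScoreModel(NetworkConfig(l_h=1, l_r=1, l_a=1, k_power=1,
                                             heads=2, hidden=8),
                               k=5, spec=spec, seed=seed)
            rng = np.random.default_rng(seed)
            t = rng.uniform(0.1, 1.0, fixture_batch.n_molecules)
            losses = dsm_losses(model, fixture_batch, t, spec, cfg, rng)
            assert losses.loss_x >= 0 and losses.loss_p >= 0 and losses.loss_a >= 0

    def test_loss_invariant_under_rigid_rotation_of_dataset(self, spec, tiny_config):
        mols = make_fixtures(FixtureSpec(count_per_template=4, jitter_std=0.05,
                                         seed=3))
        R = random_orthogonal(np.random.default_rng(5))
        rotated = [type(m)(X=m.X, P=m.P @ R, A=m.A, vocab=m.vocab) for m in mols]
        model = ScoreModel(tiny_config, k=5, spec=spec, seed=0)
        cfg = TrainConfig(seed=0)
        t = np.random.default_rng(0).uniform(0.1, 1.0, len(mols))

        # identical noise draws in the rotated frame: rotate the P-noise too
        b1 = MoleculeBatch.from_molecules(mols)
        b2 = MoleculeBatch.from_molecules(rotated)
        state1 = perturb(b1, t, spec, np.random.default_rng(11))
        state2 = state1.copy()
        state2.P = state1.P @ R
        state2.t = state1.t
        from molsde.training import _component_loss, _gamma

        tg1 = conditional_score_target(b1, state1, spec)
        tg2 = conditional_score_target(b2, state2, spec)
        s1 = model.forward(state1)
        s2 = model.forward(state2)
        g = _gamma(cfg.gamma, spec.schedule_p, t)
        l1 = _component_loss(s1[1], tg1.P, b1.mask[..., None], g, "P")
        l2 = _component_loss(s2[1], tg2.P, b2.mask[..., None], g, "P")
        assert float(l1.data) == pytest.approx(float(l2.data), rel=1e-5)


class TestTrainLoop:
    def test_smoke_training_halves_loss_on_zero_jitter_methane(self, spec,
                                                               tiny_config):
        mols = make_fixtures(FixtureSpec(templates=("methane",),
                                         count_per_template=200, jitter_std=0.0,
                                         seed=4))
        model = ScoreModel(tiny_config, k=5, spec=spec, seed=1)
        cfg = TrainConfig(steps=300, batch_size=32, lr=2e-3, ema_decay=0.9,
                          seed=5, log_every=1)
        result = train(mols, model, spec, cfg)
        early = np.mean([h["total"] for h in result.history[:10]])
        late = np.mean([h["total"] for h in result.history[-10:]])
        assert late <= 0.5 * early

    def test_fixed_seed_training_is_reproducible(self, spec, tiny_config):
        mols = make_fixtures(FixtureSpec(count_per_template=5, jitter_std=0.02,
                                         seed=6))
        finals = []
        for _ in range(2):
            model = ScoreModel(tiny_config, k=5, spec=spec, seed=2)
            cfg = TrainConfig(steps=25, batch_size=8, seed=7)
            finals.append(train(mols, model, spec, cfg).final_loss)
        assert abs(finals[0] - finals[1]) < 1e-6

    def test_ema_decay_zero_tracks_raw_weights(self, spec, tiny_config):
        mols = make_fixtures(FixtureSpec(count_per_template=3, jitter_std=0.02,
                                         seed=8))
        model = ScoreModel(tiny_config, k=5, spec=spec, seed=3)
        cfg = TrainConfig(steps=5, batch_size=4, ema_decay=0.0, seed=9)
        result = train(mols, model, spec, cfg)
        for shadow, p in zip(result.ema.shadow, model.parameters()):
            assert np.array_equal(shadow, p.data)

    def test_metrics_csv_written(self, spec, tiny_config, tmp_path):
        mols = make_fixtures(FixtureSpec(count_per_template=3, jitter_std=0.02,
                                         seed=8))
        model = ScoreModel(tiny_config, k=5, spec=spec, seed=3)
        path = tmp_path / "metrics.csv"
        train(mols, model, spec, TrainConfig(steps=10, batch_size=4, seed=0),
              metrics_path=path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "step,loss_x,loss_p,loss_a,total"
        assert len(lines) >= 3

    def test_empty_dataset_rejected(self, spec, tiny_config):
        model = ScoreModel(tiny_config, k=5, spec=spec, seed=0)
        with pytest.raises(ValueError):
            train([], model, spec, TrainConfig(steps=1))

    def test_single_atom_score_approaches_analytic_gaussian_score(self, spec):
        # dataset: one-atom molecules, X fixed one-hot, P = 0; the marginal
        # score of X at time t is -(x - alpha_t x0)/sigma_t^2
        from molsde.mol_data import Molecule

        mols = [Molecule(X=np.eye(5)[[1]], P=np.zeros((1, 3)), A=np.zeros((1, 1)))
                for _ in range(32)]
        cfg_net = NetworkConfig(l_h=1, l_r=1, l_a=1, k_power=1, heads=2, hidden=32)
        model = ScoreModel(cfg_net, k=5, spec=spec, seed=4)
        result = train(mols, model, spec,
                       TrainConfig(steps=400, batch_size=32, lr=3e-3,
                                   ema_decay=0.9, seed=10))
        batch = MoleculeBatch.from_molecules(mols[:16])
        rng = np.random.default_rng(11)
        errs = []
        with result.ema.averaged():
            for t in np.linspace(0.15, 0.9, 6):
                state = perturb(batch, float(t), spec, rng)
                alpha, sigma = spec.schedule_x.alpha_sigma(float(t))
                analytic = -(state.X - alpha * batch.X) / sigma**2
                est = model(state).X
                errs.append(np.mean((est - analytic) ** 2))
        assert np.mean(errs) < 0.1


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(steps=0)
    with pytest.raises(ValueError):
        TrainConfig(ema_decay=1.0)
    with pytest.raises(ValueError):
        TrainConfig(gamma="bogus")
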