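"""Partial-score networks: cosine-augmented EGCL stacks and pair attention.

Three time-conditioned networks estimate the partial scores of the joint
density p_t(X_t, P_t, A_t):

* the atom-type network consumes invariant features only, so its output is
  invariant under E(3) acting on the coordinates;
* the coordinate network emits a combination of displacement fields, which
  is rotation/reflection-equivariant and translation-invariant, projected
  onto the zero-CoM subspace;
* the adjacency network scores each atom pair from multi-head query/key
  products of node features plus pairwise invariants (squared distances and
  rescaled adjacency powers), symmetrized with a zero diagonal.

The equivariant graph convolution layer (EGCL) augments the usual
(d_ij^2, a_ij) edge invariants with the cosine between the CoM-centered
position vectors p_i and p_j.  On the zero-CoM subspace this cosine is
invariant to the whole of E(3), and it carries angular information that
squared distances alone do not.  The per-edge learnable functions are:

    v_ij  = phi_ax(x_i, x_j, d_ij^2, cos(p_i, p_j), a_ij)
    x_i'  = phi_x(x_i, sum_{j != i} sigmoid(phi_a(v_ij)) v_ij)
    p_i'  = p_i + sum_{j != i} (p_i - p_j) / (d_ij + 1)
                  * phi_ap(x_i, x_j, d_ij^2, cos(p_i, p_j), a_ij)

Ablation toggles mirror the framework's variants: ``use_cosine=False``
drops the cosine feature, ``use_equivariant=False`` swaps the EGCL for a
plain message-passing layer over raw coordinates (intentionally breaking
equivariance), and ``fused_xp_network=True`` emits the atom-type and
coordinate scores from one shared stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, no_grad, sigmoid, sqrt, tensor
from .nn import MLP, LayerNorm, Linear, Module
from .sde import DiffusionSpec, NoisedState, PartialScores

__all__ = [
    "NetworkConfig",
    "EGCL",
    "NonEquivariantLayer",
    "ScoreXNet",
    "ScorePNet",
    "ScoreANet",
    "FusedXPNet",
    "ScoreModel",
    "adjacency_powers",
]

_EPS_COS = 1e-8


@dataclass(frozen=True)
class NetworkConfig:
    """Layer counts, widths and ablation toggles for the three score networks."""

    l_h: int = 4  # EGCL layers of the atom-type stack
    l_r: int = 4  # displacement-field levels of the coordinate stack
    l_a: int = 4  # attention levels of the adjacency network
    k_power: int = 3  # max adjacency power K
    heads: int = 4
    hidden: int = 128
    egnn_depth: int = 2  # EGCLs chained inside each coordinate-level EGNN
    use_cosine: bool = True
    use_equivariant: bool = True
    fused_xp_network: bool = False

    def __post_init__(self):
        for name in ("l_h", "l_r", "l_a", "k_power", "heads", "hidden",
                     "egnn_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------
# helpers on taped tensors
# ---------------------------------------------------------------------------


def _pair_mask(mask: np.ndarray) -> np.ndarray:
    n = mask.shape[1]
    return (mask[:, :, None] * mask[:, None, :] * (1.0 - np.eye(n)[None]))[..., None]


def _project_com(p: Tensor, mask: np.ndarray) -> Tensor:
    """Masked zero-CoM projection of a (B, N, 3) tensor."""
    m = mask[..., None]
    counts = np.maximum(mask.sum(axis=1), 1.0)[:, None, None]
    mean = (p * m).sum(axis=1, keepdims=True) / counts
    return (p - mean) * m


def _check_symmetric(A: np.ndarray) -> None:
    if not np.allclose(A, np.swapaxes(A, -1, -2), atol=1e-8):
        raise ValueError("adjacency input must be symmetric")


def _expand_pairs(x: Tensor) -> tuple[Tensor, Tensor]:
    b, n, h = x.shape
    xi = x.reshape(b, n, 1, h).broadcast_to((b, n, n, h))
    xj = x.reshape(b, 1, n, h).broadcast_to((b, n, n, h))
    return xi, xj


def _pair_geometry(p: Tensor, use_cosine: bool):
    """(diff, d, d2, cos) pairwise geometry of a (B, N, 3) coordinate tensor."""
    b, n, _ = p.shape
    diff = p.reshape(b, n, 1, 3) - p.reshape(b, 1, n, 3)
    d2 = (diff * diff).sum(axis=-1, keepdims=True)
    d = sqrt(d2 + 1e-16)
    cos = None
    if use_cosine:
        dots = (p.reshape(b, n, 1, 3) * p.reshape(b, 1, n, 3)).sum(axis=-1, keepdims=True)
        norm = sqrt((p * p).sum(axis=-1, keepdims=True) + 1e-16)
        ni = norm.reshape(b, n, 1, 1).broadcast_to((b, n, n, 1))
        nj = norm.reshape(b, 1, n, 1).broadcast_to((b, n, n, 1))
        cos = dots / (ni * nj + _EPS_COS)
    return diff, d, d2, cos


class EGCL(Module):
    """One cosine-augmented equivariant graph convolution layer."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 use_cosine: bool = True):
        pair_in = 2 * in_dim + 2 + (1 if use_cosine else 0)
        self.edge_mlp = MLP([pair_in, hidden, hidden], rng, final_activation=True)
        self.edge_norm = LayerNorm(hidden)
        self.gate = Linear(hidden, 1, rng)
        self.node_mlp = MLP([in_dim + hidden, hidden, hidden], rng)
        self.node_norm = LayerNorm(hidden)
        self.coord_mlp = MLP([pair_in, hidden, hidden, 1], rng)
        self.use_cosine = use_cosine

    def __call__(self, x: Tensor, p: Tensor, A, mask: np.ndarray,
                 layer_index: int = 0, update_feats: bool = True,
                 update_coords: bool = True) -> tuple[Tensor, Tensor]:
        A = tensor(A)
        _check_symmetric(A.data)
        x, p = tensor(x), tensor(p)
        pm = _pair_mask(mask)
        diff, d, d2, cos = _pair_geometry(p, self.use_cosine)
        xi, xj = _expand_pairs(x)
        a_feat = A.reshape(A.shape[0], A.shape[1], A.shape[2], 1)
        parts = [xi, xj, d2, cos, a_feat] if cos is not None else [xi, xj, d2, a_feat]
        feats = concat(parts, axis=-1)
        x_new, p_new = x, p
        if update_feats:
            v = self.edge_norm(self.edge_mlp(feats))
            gated = sigmoid(self.gate(v)) * v * pm
            agg = gated.sum(axis=2)
            x_new = self.node_norm(
                self.node_mlp(concat([x, agg], axis=-1))
            ) * mask[..., None]
        if update_coords:
            w = self.coord_mlp(feats) * pm
            p_new = (p + (diff / (d + 1.0) * w).sum(axis=2)) * mask[..., None]
        if not (np.all(np.isfinite(x_new.data)) and np.all(np.isfinite(p_new.data))):
            raise FloatingPointError(f"non-finite output of EGCL layer {layer_index}")
        return x_new, p_new


class NonEquivariantLayer(Module):
    """Plain message passing on raw coordinates (the non-equivariant ablation).

    Messages and the coordinate update consume the Cartesian coordinates
    directly, so the layer has no E(3) symmetry.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 use_cosine: bool = True):
        del use_cosine  # geometry enters raw; the cosine toggle has no meaning here
        pair_in = 2 * in_dim + 6 + 1
        self.edge_mlp = MLP([pair_in, hidden, hidden], rng, final_activation=True)
        self.gate = Linear(hidden, 1, rng)
        self.node_mlp = MLP([in_dim + hidden, hidden, hidden], rng)
        self.coord_mlp = MLP([hidden + 3, hidden, 3], rng)

    def __call__(self, x: Tensor, p: Tensor, A, mask: np.ndarray,
                 layer_index: int = 0, update_feats: bool = True,
                 update_coords: bool = True) -> tuple[Tensor, Tensor]:
        A = tensor(A)
        _check_symmetric(A.data)
        x, p = tensor(x), tensor(p)
        pm = _pair_mask(mask)
        xi, xj = _expand_pairs(x)
        pi, pj = _expand_pairs(p)
        a_feat = A.reshape(A.shape[0], A.shape[1], A.shape[2], 1)
        feats = concat([xi, xj, pi, pj, a_feat], axis=-1)
        v = self.edge_mlp(feats)
        agg = (sigmoid(self.gate(v)) * v * pm).sum(axis=2)
        x_new = (
            self.node_mlp(concat([x, agg], axis=-1)) * mask[..., None]
            if update_feats
            else x
        )
        p_new = (
            (p + self.coord_mlp(concat([agg, p], axis=-1))) * mask[..., None]
            if update_coords
            else p
        )
        return x_new, p_new


def _make_layer(cfg: NetworkConfig, in_dim: int, rng: np.random.Generator):
    cls = EGCL if cfg.use_equivariant else NonEquivariantLayer
    return cls(in_dim, cfg.hidden, rng, use_cosine=cfg.use_cosine)


def _time_features(X: Tensor, t: np.ndarray, T: float, mask: np.ndarray) -> Tensor:
    """H_0 = [X_t, t/T] per node, masked."""
    b, n, _ = X.shape
    tcol = np.broadcast_to((t / T)[:, None, None], (b, n, 1)) * mask[..., None]
    return concat([X, tensor(tcol)], axis=-1)


# ---------------------------------------------------------------------------
# score networks
# ---------------------------------------------------------------------------


class ScoreXNet(Module):
    """Atom-type partial score: EGCL feature stack + MLP over all depths.

    The output consumes invariant features only, hence is invariant under
    rotations/reflections of P_t and equivariant under atom permutations.
    """

    def __init__(self, cfg: NetworkConfig, k: int, T: float, rng: np.random.Generator):
        in0 = k + 1
        self.layers = [
            _make_layer(cfg, in0 if i == 0 else cfg.hidden, rng) for i in range(cfg.l_h)
        ]
        self.out_mlp = MLP([in0 + cfg.l_h * cfg.hidden, cfg.hidden, k], rng)
        self.T = T

    def __call__(self, X, P, A, t, mask) -> Tensor:
        h = _time_features(tensor(X), t, self.T, mask) * mask[..., None]
        hs = [h]
        p = tensor(P)
        for i, layer in enumerate(self.layers):
            h, _ = layer(h, p, A, mask, layer_index=i, update_coords=False)
            hs.append(h)
        return self.out_mlp(concat(hs, axis=-1)) * mask[..., None]


class _EGNN(Module):
    """A chain of EGCLs updating features and coordinates jointly."""

    def __init__(self, cfg: NetworkConfig, in_dim: int, rng: np.random.Generator,
                 depth: int):
        self.layers = [
            _make_layer(cfg, in_dim if j == 0 else cfg.hidden, rng)
            for j in range(depth)
        ]

    def __call__(self, h: Tensor, p: Tensor, A, mask: np.ndarray,
                 update_feats_last: bool = True) -> tuple[Tensor, Tensor]:
        last = len(self.layers) - 1
        for j, layer in enumerate(self.layers):
            h, p = layer(
                h, p, A, mask, layer_index=j,
                update_feats=(j < last or update_feats_last),
            )
        return h, p


class ScorePNet(Module):
    """Coordinate partial score as a combination of displacement fields.

    Each level peels off its input: R_{i+1} = EGNN([X_t, t/T], R_i, A_t) - R_i,
    a translation-invariant, rotation/reflection-equivariant field; the
    per-level EGNN is a chain of ``egnn_depth`` EGCLs.  The fields are
    combined with per-node scalar weights computed from invariant features
    only, then projected onto the zero-CoM subspace.  (An MLP over
    concatenated raw coordinate stacks would break equivariance; scalar
    weighting of equivariant fields is the equivariance-preserving reading.)
    """

    def __init__(self, cfg: NetworkConfig, k: int, T: float, rng: np.random.Generator):
        in0 = k + 1
        self.levels = [
            _EGNN(cfg, in0, rng, cfg.egnn_depth) for _ in range(cfg.l_r)
        ]
        self.weight_mlp = MLP([in0, cfg.hidden, cfg.l_r], rng)
        self.T = T

    def __call__(self, X, P, A, t, mask) -> Tensor:
        P = tensor(P)
        counts = np.maximum(mask.sum(axis=1), 1.0)[:, None]
        coms = np.abs((P.data * mask[..., None]).sum(axis=1)) / counts
        scale = max(1.0, float(np.max(np.abs(P.data))))
        if coms.max() > 1e-6 * scale:  # relative: projection is float-exact only
            raise ValueError(
                f"input coordinates must be CoM-free (|CoM| = {coms.max():.2e})"
            )
        h0 = _time_features(tensor(X), t, self.T, mask) * mask[..., None]
        r = P
        fields = []
        for level in self.levels:
            _, p_out = level(h0, r, A, mask, update_feats_last=False)
            r = _project_com(p_out - r, mask)
            fields.append(r)
        w = self.weight_mlp(h0)  # (B, N, l_r), invariant
        out = fields[0] * w[:, :, 0:1]
        for i in range(1, len(fields)):
            out = out + fields[i] * w[:, :, i : i + 1]
        return _project_com(out, mask)


def adjacency_powers(A, K: int):
    """Matrix powers A^1..A^K, each rescaled by its max |entry| (+eps).

    Power c encodes c-hop connectivity; the rescaling keeps the feature
    range comparable across powers.  Accepts (N, N) or (B, N, N) input.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    A_t = tensor(A)
    _check_symmetric(A_t.data)
    powers = []
    current = A_t
    for _ in range(K):
        scale = np.max(np.abs(current.data), axis=(-2, -1), keepdims=True) + 1e-8
        powers.append(current / scale)
        current = current @ A_t
    return powers


class ScoreANet(Module):
    """Adjacency partial score via graph multi-head attention over A powers.

    A node track H_i (EGCL features) and a displacement track R_i feed
    per-level query/key head products; each (level i, power c) block
    contributes per-pair features [QK products per head, |R_i differences|^2,
    (A^c)_ij].  All blocks concatenate into an MLP producing one value per
    pair, symmetrized as (S + S^T)/2 with zero diagonal.  Only invariant
    functions of the coordinates are consumed, so the output is invariant
    under E(3) and equivariant under permutations.
    """

    def __init__(self, cfg: NetworkConfig, k: int, T: float, rng: np.random.Generator):
        in0 = k + 1
        self.h_layers = [
            _make_layer(cfg, in0 if i == 0 else cfg.hidden, rng) for i in range(cfg.l_a)
        ]
        self.r_layers = [_make_layer(cfg, in0, rng) for _ in range(cfg.l_a)]
        dims = [in0] + [cfg.hidden] * cfg.l_a
        if cfg.heads > 1 and cfg.hidden % cfg.heads != 0:
            raise ValueError("hidden width must be divisible by the head count")
        self.q_proj = [Linear(d, cfg.hidden, rng) for d in dims]
        self.k_proj = [Linear(d, cfg.hidden, rng) for d in dims]
        n_feats = (cfg.l_a + 1) * cfg.k_power * (cfg.heads + 2)
        self.out_mlp = MLP([n_feats, cfg.hidden, 1], rng)
        self.cfg = cfg
        self.T = T

    def _attention_pairs(self, h: Tensor, level: int) -> Tensor:
        b, n, _ = h.shape
        heads = self.cfg.heads
        dh = self.cfg.hidden // heads
        q = self.q_proj[level](h).reshape(b, n, heads, dh).transpose((0, 2, 1, 3))
        k = self.k_proj[level](h).reshape(b, n, heads, dh).transpose((0, 2, 3, 1))
        e = (q @ k) / np.sqrt(dh)  # (B, heads, N, N)
        return e.transpose((0, 2, 3, 1))  # (B, N, N, heads)

    def __call__(self, X, P, A, t, mask) -> Tensor:
        cfg = self.cfg
        pm = _pair_mask(mask)
        h0 = _time_features(tensor(X), t, self.T, mask) * mask[..., None]
        p = tensor(P)
        hs, d2s = [h0], []
        _, _, d2_0, _ = _pair_geometry(p, use_cosine=False)
        d2s.append(d2_0)
        h, r = h0, p
        for i in range(cfg.l_a):
            h, _ = self.h_layers[i](h, p, A, mask, layer_index=i, update_coords=False)
            _, p_out = self.r_layers[i](h0, r, A, mask, layer_index=i, update_feats=False)
            r = _project_com(p_out - r, mask)
            hs.append(h)
            _, _, d2_i, _ = _pair_geometry(r, use_cosine=False)
            d2s.append(d2_i)
        a_pows = adjacency_powers(A, cfg.k_power)
        blocks = []
        for i in range(cfg.l_a + 1):
            e_i = self._attention_pairs(hs[i], i)
            for c in range(cfg.k_power):
                a_c = a_pows[c]
                a_feat = a_c.reshape(a_c.shape[0], a_c.shape[1], a_c.shape[2], 1)
                blocks.append(concat([e_i, d2s[i], a_feat], axis=-1))
        s = self.out_mlp(concat(blocks, axis=-1))  # (B, N, N, 1)
        s = s.reshape(s.shape[:-1])
        s = (s + s.swapaxes(-1, -2)) * 0.5
        return s * pm[..., 0]


class FusedXPNet(Module):
    """Single shared stack emitting both the atom-type and coordinate scores
    (the fused-network ablation)."""

    def __init__(self, cfg: NetworkConfig, k: int, T: float, rng: np.random.Generator):
        in0 = k + 1
        n_layers = max(cfg.l_h, cfg.l_r)
        self.layers = [
            _make_layer(cfg, in0 if i == 0 else cfg.hidden, rng)
            for i in range(n_layers)
        ]
        self.out_mlp = MLP([in0 + n_layers * cfg.hidden, cfg.hidden, k], rng)
        self.weight_mlp = MLP([in0, cfg.hidden, n_layers], rng)
        self.T = T

    def __call__(self, X, P, A, t, mask) -> tuple[Tensor, Tensor]:
        h = _time_features(tensor(X), t, self.T, mask) * mask[..., None]
        h0 = h
        r = tensor(P)
        hs, fields = [h], []
        for i, layer in enumerate(self.layers):
            h, p_out = layer(h, r, A, mask, layer_index=i)
            r = _project_com(p_out - r, mask)
            hs.append(h)
            fields.append(r)
        score_x = self.out_mlp(concat(hs, axis=-1)) * mask[..., None]
        w = self.weight_mlp(h0)
        score_p = fields[0] * w[:, :, 0:1]
        for i in range(1, len(fields)):
            score_p = score_p + fields[i] * w[:, :, i : i + 1]
        return score_x, _project_com(score_p, mask)


class ScoreModel(Module):
    """The three partial-score networks behind one interface.

    The networks emit bounded fields on the noise scale; the model divides
    each component by sigma_c(t), so the regression target under the
    sigma^2 loss weighting is the (bounded) negative noise while the
    returned quantity is the partial score itself.  ``forward`` returns
    taped tensors for training; calling the model returns plain-numpy
    :class:`PartialScores` without building a graph.
    """

    def __init__(self, config: NetworkConfig, k: int,
                 spec: DiffusionSpec | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.k = k
        self.spec = spec if spec is not None else DiffusionSpec()
        T = self.spec.T
        self.T = T
        if config.fused_xp_network:
            self.fused = FusedXPNet(config, k, T, rng)
        else:
            self.net_x = ScoreXNet(config, k, T, rng)
            self.net_p = ScorePNet(config, k, T, rng)
        self.net_a = ScoreANet(config, k, T, rng)

    def forward(self, state: NoisedState) -> tuple[Tensor, Tensor, Tensor]:
        X, P, A, t, mask = state.X, state.P, state.A, state.t, state.mask
        if self.config.fused_xp_network:
            sx, sp = self.fused(X, P, A, t, mask)
        else:
            sx = self.net_x(X, P, A, t, mask)
            sp = self.net_p(X, P, A, t, mask)
        sa = self.net_a(X, P, A, t, mask)
        def inv_sigma(schedule):
            _, sigma = schedule.alpha_sigma(t)
            return (1.0 / sigma)[:, None, None]
        sx = sx * inv_sigma(self.spec.schedule_x)
        sp = sp * inv_sigma(self.spec.schedule_p)
        sa = sa * inv_sigma(self.spec.schedule_a)
        return sx, sp, sa

    def __call__(self, state: NoisedState) -> PartialScores:
        with no_grad():
            sx, sp, sa = self.forward(state)
        return PartialScores(X=sx.data, P=sp.data, A=sa.data)
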