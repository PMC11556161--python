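# Methods

This note records the model, the numerical choices, and the boundaries of
what the bundled experiments demonstrate.

## State space and symmetry

A molecule is M = (X, P, A): one-hot atom types X (N×k, default alphabet
H/C/N/O/F with valencies 1/4/3/2/1), coordinates P (N×3, Å) and a
symmetric bond-order matrix A (N×N, orders 0–3, zero diagonal). The
likelihood of a 3D molecule should be invariant to translations,
rotations, reflections and atom relabelings. Translations are handled by
construction: coordinates are projected to the zero center-of-mass (CoM)
subspace on ingest and every coordinate-valued operation (noise draws,
network outputs, solver updates) re-projects, so the whole generative
process lives on that subspace — there is no normalizable
translation-invariant density on the full space. Rotations/reflections
and permutations are handled by network equivariance: an invariant prior
plus equivariant reverse kernels yields an invariant model distribution.

Variable molecule sizes are batched by zero-padding with a per-molecule
node mask; masked entries contribute exactly zero to messages, losses and
norms, which the test suite asserts.

## Forward diffusion

Each component follows an independent variance-preserving SDE
du = −½β_c(t) u dt + √β_c(t) dw on t ∈ [0, 1], with β_c(t) linear from
β_min = 0.1 to β_max = 20 (all three components share these defaults;
they are package choices, as is the VP form itself — chosen because it
gives a standard-normal prior and closed-form kernels
u_t ~ N(α_t u_0, σ_t² I), α_t = exp(−½∫β), σ_t² = 1 − α_t²).
Component conventions: coordinate noise is mean-subtracted per axis
(stays on the zero-CoM subspace, entry variance (N−1)/N), adjacency noise
is drawn on the strict upper triangle and mirrored (symmetric, unit
entry variance, zero diagonal).

## Score networks

All three networks are conditioned on t by concatenating t/T to the node
features and emit **noise-scale fields divided by σ_c(t)**: the network
output is bounded like −ε while the returned quantity is the score
−ε/σ. Without this parameterization the networks would need outputs of
magnitude 1/σ ≈ 10³ near t_min, which is what made early reverse runs
diverge.

The cosine-augmented EGCL computes per-edge messages from
(x_i, x_j, d_ij², cos(p_i, p_j), a_ij), where cos is taken between
CoM-centered position vectors with an ε = 1e-8 norm guard; on the
zero-CoM subspace this cosine is invariant to all of E(3). Gating is a
sigmoid on a learned scalar per edge (the standard EGNN attention form);
hidden activations are SiLU, and the message and feature outputs pass
through layer normalization (invariant channels only, so the symmetry
contracts are untouched; it markedly reduced run-to-run variance of the
learned geometry). The coordinate update moves p_i along
(p_i − p_j)/(d_ij + 1) with a learned scalar weight per edge.

* **score_X**: L_H EGCL feature layers over (H_i, P_t, A_t) starting from
  H_0 = [X_t, t/T]; the output MLP reads the concatenation of all depths.
  Consumes invariants only ⇒ rotation/reflection-invariant.
* **score_P**: L_R levels of R_{i+1} = EGNN([X_t, t/T], R_i, A_t) − R_i
  with R_0 = P_t. Each level's EGNN is a chain of `egnn_depth` EGCLs
  updating features and coordinates jointly; subtracting the level input
  makes each field translation-invariant. Fields are combined with
  per-node scalar weights computed from invariant features only and the
  sum is projected to zero CoM. A literal MLP over concatenated
  coordinate stacks would destroy equivariance, so the scalar-weighted
  combination is the deliberate, equivariance-preserving design. The
  inner depth matters: displacement-on-displacement levels beyond the
  first never see the actual molecular geometry again, and measured
  coordinate-score error stayed flat when only levels were added but
  dropped when depth inside the first level was added.
* **score_A**: a feature track H_i and a displacement track R_i feed
  per-level multi-head query/key products; each (level, power) block
  contributes [QK per head, pairwise |ΔR_i|², rescaled (A^c)_ij]. The
  concatenated blocks map through an MLP to one value per pair,
  symmetrized as (S+Sᵀ)/2 with zero diagonal. Adjacency powers are
  rescaled by their max absolute entry to keep feature ranges comparable.
  Only invariant functions of coordinates enter ⇒ E(3)-invariant.

Ablation toggles reproduce the framework variants structurally:
`use_cosine=False` drops the cosine feature (networks stay equivariant),
`use_equivariant=False` swaps the EGCL for plain message passing over raw
coordinates (the test battery asserts this variant *fails* equivariance),
`fused_xp_network=True` emits score_X and score_P from one shared stack.

Full-scale defaults are L_H = L_R = L_A = 4, K = 3 adjacency powers,
4 heads, width 128; none of these are literature-reported values — layer
counts and widths for the original experiments are not public, so the
defaults are package choices.

## Training

Denoising score matching with the separated Gaussian transition kernels:
per component, γ_c(t)·‖s_c(M_t) − (−(u_t − α_t u_0)/σ_t²)‖², summed per
molecule over unmasked entries, averaged over the batch, with one
t ~ U[t_min, T] per molecule (t_min = 1e-5 avoids the σ→0 singularity).
γ_c(t) = σ_{c,t}² by default (bounded ε-regression); `g_sq` and `uniform`
weightings are selectable. The three objectives are independent; a single
Adam optimizer (lr 2e-3, cosine-decayed to 5%, global-norm clip 1.0)
steps their disjoint parameter sets jointly, which is equivalent to three
separate optimizers. An EMA shadow (decay 0.999 full-scale, 0.99 at desk
scale where runs are short) provides the sampling weights. Batches draw
one molecule size per step (probability proportional to the size's share
of the dataset), which avoids padding waste without changing the sampled
distribution; bucket probabilities can additionally be weighted by
molecule size (`bucket_size_power`), giving the harder large-N
conditional models proportionally more steps — generation-time sizes
come from the dataset's empirical distribution, so this reallocates
optimization effort without changing what is modeled. Optionally a
fraction of each batch's time draws is taken from a low-noise window
[t_min, 0.25] (`t_low_fraction`): the low-σ regime is where sub-0.1 Å
geometric precision is learned, and uniform t sampling gives it little
effective weight. Training is deterministic given the config seed on one
device.

## Sampling and decoding

Predictor–Corrector on a uniform time grid from T to t_min = 1e-3:
reverse Euler–Maruyama predictor, then M Langevin corrector steps with
step size η = 2(r‖ξ‖/‖s‖)², where the norms are per-sample norms
averaged over the batch — per-chain norms make η ∝ 1/‖s‖² explode when an
individual chain crosses a score zero. Defaults n_steps = 1000, M = 1,
r = 0.16 (standard PC practice). The final move is conditional-mean
(Tweedie) denoising, u_0 ≈ (u + σ²s)/α, instead of one more noise-adding
step. A magnitude guard clips the state to ±100 (legitimate states stay
within a few units); it only ever activates for untrained or diverging
models and keeps the pipeline total. Decoding: argmax atom types (ties
to the lowest vocabulary index), adjacency symmetrized, clipped to
[0, 3], rounded half-up, coordinates re-centered. The number of atoms for
each sample is drawn from the empirical size distribution of the training
set — how N is chosen at generation time is not specified in the source
framework, so the empirical distribution is this package's choice.

One property of the corrector worth knowing: unadjusted Langevin has a
stationary bias of order r² that does not shrink with the time grid, so
grid-refinement convergence of the solver is measured with the corrector
off; with it on, absolute moment accuracy is still comfortably within
the tested tolerances.

## Evaluation

Validity = fraction of generated molecules whose bond graph sanitizes
under RDKit; valid & unique = distinct canonical SMILES among the valid
molecules divided by all generated; atom stability = atoms whose summed
incident bond orders equal their element valency; molecule stability =
molecules with all atoms stable. Bonds are taken from geometry by
default (distance + atom types against a shipped covalent bond-length
table, ±0.1 Å margins per order), mirroring the common evaluation
protocol; a flag scores the generated adjacency instead. Within the
margin brackets the order closest to its reference length wins — the
brackets of adjacent orders overlap (C=O at 1.21 Å also lies in the C≡O
bracket), and nearest-reference selection is what makes ideal-geometry
molecules map back to their true orders. Bond-length histograms use
0.01 Å bins, bond-angle histograms 2° bins.

SDF reading does not require sanitization: chemically invalid molecules
must be representable, because the metrics have to score them.

## Synthetic fixtures and what the toy experiments show

The fixture generator emulates a peaked molecular dataset: rigid
ideal-geometry templates (hydrogen fluoride, water, ammonia,
formaldehyde, methane, ethylene, ethane) with isotropic Gaussian
coordinate jitter, re-centered; adjacency and types are copied from the
template. The desk-scale study conditions are four templates with
pairwise-distinct sizes (water 3, formaldehyde 4, methane 5, ethylene 6),
jitter 0.02 Å, 100 molecules per template, and 200 generated samples.

Desk-scale problem sizes (the `recipes` module): width 64, three EGCL
layers in the atom-type stack, two displacement levels of inner depth 2,
two attention levels, K = 2, 2 heads; 5000 training steps with batch 56,
30% low-t emphasis and size-weighted buckets; a 300-step quadratic
(low-noise-dense) PC grid with M = 2 correctors plus 30 final Langevin
polish steps. A full cycle runs in roughly a quarter hour on one CPU
core.

What passing toy runs do show: the coupled three-component diffusion,
the equivariant score estimation, the PC solver and the decoding
pipeline are implemented correctly and can learn and reproduce a peaked
3D molecular distribution, including exact bond-graph recovery and
geometry accurate enough for distance-based bond re-derivation. What
they do not show: generalization across chemical space, performance on
multimodal conformer distributions, or any quantitative claim at QM9
scale — those require orders of magnitude more training than a
CPU-minutes budget provides.

## Degenerate inputs and numerical edges

Single-atom molecules have zero CoM by definition and empty pair sets;
messages and pair losses are empty sums (exact zeros). t = 0 perturbation
returns the data exactly; the conditional score is undefined there and
raises. Zero-norm position vectors in the cosine are guarded by ε.
Argmax ties in decoding break to the lowest vocabulary index. The
corrector skips identically-zero scores (logged once). All computation
is float64; the equivariance battery asserts 1e-5 relative error, which
float32 round-off would consume.

## Known limitations

* The score networks carry some structurally dead parameters (e.g. the
  coordinate MLP of feature-only stacks); they are never touched by
  gradients and exist to keep one layer type serving all stacks.
* The Langevin corrector is unadjusted (no Metropolis correction); its
  O(r²) stationary bias is visible in high-precision solver tests.
* Geometry-inferred bond typing is a nearest-bracket rule on pair
  distances; it does not consider conjugation or resonance.
* NLL/likelihood computation and probability-flow ODE sampling are not
  implemented (out of scope); potential-energy distributions would need
  an external force field and are provided only as evaluation hooks the
  tests do not cover.
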