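# Methods

`ribodesign` implements fixed-backbone RNA sequence design ("inverse
folding") as conditional generative modelling: given the tertiary-structure
backbone **X** of an RNA chain, sample sequences **S** from a learned
conditional distribution p(S | X) rather than predicting a single most-likely
sequence.  This note records the model, the numerical choices, and what the
desk-scale experiments do and do not demonstrate.

## Problem representation

Each nucleotide is reduced to three atoms: C4′, C1′, and the glycosidic
nitrogen (N9 for purines A/G, N1 for pyrimidines C/U), so a chain of N
nucleotides is a coordinate array X ∈ R^(N×3×3) in Å.  The sequence
S ∈ {A,U,C,G}^N is one-hot encoded as an N×4 real matrix (column order
A, C, G, U) and treated as continuous data for the diffusion process.
Nucleotides missing any of the three atoms are dropped at parse time;
modified/unknown residues read as `N` and such chains are excluded from
training by default, because the model alphabet is strictly four-letter.
Dataset assembly filters chains to 20–280 nt, inclusive at both ends.

## Diffusion model

Forward process (variance preserving):
q(S_t | S_0) = N(α_t S_0, σ_t² I) on t ∈ (0, 1], with α_t² + σ_t² = 1 and a
strictly decreasing signal-to-noise ratio SNR(t) = α_t²/σ_t²;
λ_t = log SNR(t) is the network's time conditioning.

* **Default schedule** — "trimmed cosine": α_t = cos(0.99·(π/2)·t).  The
  0.99 trim keeps α_1 ≈ 0.016 > 0 so the SNR is strictly decreasing on all
  of (0,1] with no clipping plateau, while the terminal marginal is within
  ~10⁻⁴ of N(0, I).  A linear-β VP schedule (β ∈ [0.1, 20]) is available as
  `get_schedule("linear")`.
* **Training objective** — the data-prediction network d_θ(S_t, λ_t, X)
  estimates S_0 and is fit by the weighted squared error
  (α_t/σ_t)·‖d_θ − S_0‖², with t drawn uniformly per example from
  (t_min, 1], t_min = 10⁻³ (numerical guard against the λ → ∞ end).
* **Sampling** — exact Gaussian ancestral steps on a strictly decreasing
  grid (default 50 uniform steps from 1.0 to 10⁻³).  With
  α_{t|s} = α_t/α_s and σ_{t|s}² = σ_t² − α_{t|s}² σ_s², the step is
  mean = (α_{t|s} σ_s²/σ_t²) S_t + (α_s σ_{t|s}²/σ_t²) Ŝ_0, plus
  (σ_{t|s} σ_s/σ_t)·ε noise; the terminal read-out is the predicted mean of
  the last step, decoded by per-position argmax (ties resolve to the
  alphabetically first letter).  One-hot levels are {0, 1}; scaling is left
  to the network.
* **Classifier-free guidance** — the sampler can mix conditional and
  unconditional predictions, w·d_cond + (1−w)·d_uncond.  w = 1 is the pure
  conditional model; lowering w (0.5–0.35 is a sensible range) trades
  sequence recovery for diversity of the generated set.  Both branches share
  one self-conditioning buffer (the guided estimate), a choice made because
  guidance operates on data predictions; the alternative (separate buffers)
  would double the state carried through sampling for little expected gain.

## Network

**Structure module (GVP message passing).**  The chain becomes a directed
k-NN graph over nucleotides (k = 20 by default) using C1′–C1′ distances,
ties broken toward the lower residue index (distances rounded to 10⁻⁶ Å so
exact geometric ties survive floating-point jitter of a rigid motion).
Node scalars: sin/cos of four pseudo-dihedrals — two η/θ-style angles over
sliding windows of four consecutive C1′ atoms and two angles orienting the
(C4′, C1′, N) triad against the adjacent C1′ atoms — plus radial-basis
encodings (8 centers on [0.8, 3.2] Å) of the C1′–C4′ and C1′–N bond lengths
and two bond-angle cosines.  The bond-length scalars are included because in
a three-atom representation the glycosidic/ribose bond geometry is the only
per-nucleotide information that unit orientation vectors discard; they are
SE(3)-invariant and can be disabled (`FeatureConfig(bond_scalars=False)`).
Node vectors (unit length, zero-padded at termini): forward and reverse
chain directions, C1′→C4′, C1′→N.  Edge features: unit C1′→C1′ direction,
a 32-center Gaussian RBF of the distance on [0, 40] Å (width = center
spacing), and 16 sinusoidal frequency pairs of the signed sequence offset
clipped to ±64.  Three GVP layers pass messages (edge-message GVP, mean
aggregation, residual + LayerNorm on scalars, pointwise node GVP); scalar
and vector channels interact through norm features and sigmoid gating, so
scalar outputs are rotation/translation invariant and vector channels
equivariant.  Only scalar channels are read out.  The last layer's pointwise
GVP emits scalars only (its vector output could never reach the read-out).

**Sequence module (adaLN Transformer).**  Tokens are a linear projection of
[structure embedding, S_t, self-conditioning estimate].  Four pre-norm
blocks use adaptive layer norm, adaLN(h, C) = (1 + MLP₁(C))·LN(h) + MLP₂(C),
and gated activations act(h, C) = MLP₃(C)·h, with the context C an MLP
embedding of λ_t/8.  Conditioning heads initialize near zero (gates near
one) so an untrained block is close to a plain pre-norm Transformer block.
A final LayerNorm + MLP projects to 4 channels.

**Condition dropout.**  The unconditional branch replaces the structure
embedding with a learned per-position null token; feeding zero coordinates
instead would make dihedral features degenerate.  During training the
structure is dropped per example with probability 0.4, and with probability
0.5 a no-gradient pre-pass supplies the self-conditioning input (both flags
drawn independently, self-conditioning first; the pre-pass is always
conditional).  Self-conditioning is concatenated to the S_t channels (8
sequence channels at the input), initialized to zeros.

**Sizes.**  Defaults: 3 GVP layers, 4 Transformer blocks, 64 scalar and 8
vector channels, 4 heads, FFN 256.  These are set for single-CPU training of
the desk-scale experiments below in a couple of minutes; everything is
configurable upward through `DenoiserConfig`.  Optimization uses Adam
(lr 10⁻³–2·10⁻³ in the examples) with global gradient-norm clipping at 10;
no EMA or LR schedule by default.

The network and its training run on a small reverse-mode automatic
differentiation engine over NumPy arrays (`ribodesign.nn`), providing the
~25 operations the architecture needs (broadcast arithmetic, batched matmul,
gather/segment-sum for message passing, fused softmax/layer-norm).
Gradients are verified against central finite differences in the test suite.
Batches are processed as one disjoint-union graph (structure module) with
per-chain attention blocks (sequence module), which keeps CPU step times
dominated by large matrix products rather than Python overhead.

## Metrics and splits

* **Recovery rate** — fraction of positions where a generated sequence
  matches the native one; random guessing gives 0.25.
* **Sequence similarity** — identity-scored global alignment with zero gap
  penalties (equivalently, longest-common-subsequence length) divided by the
  shorter length; local alignment is available by option.
* **IntDiv** — 1 minus the mean similarity over all ordered pairs of the
  generated set, self-pairs included (|G|² normalizer, per the printed
  formula; the |G|(|G|−1) alternative would shift all values up by
  (1−0)/|G| for identical sets and is not used).
* **Base-pair F1** — precision/recall/F1 on exact (i, j) pair matches
  between two base-pair sets (e.g. parsed from dot-bracket strings, with
  per-bracket-type stacks so pseudoknots survive).  Two empty sets count as
  perfect agreement (1.0), configurable.
* **Length categories** — short ≤ 50 nt < medium ≤ 100 nt < long.
* **Splits** — items are clustered by average-linkage agglomerative
  clustering on 1 − similarity, cut at the similarity threshold, and whole
  clusters are assigned to train/valid/test (15%/10% by cluster count,
  floor rounding, remainder to train).  Multiple evaluation splits with
  pairwise-disjoint test+valid sets are built by partitioning one shuffled
  cluster order into consecutive blocks.  Outputs of external clustering and
  structure-alignment tools are ingested as plain-text cluster files and
  labeled similarity matrices; those tools are not re-implemented here.

## Synthetic fixtures and what they show

Real-corpus training needs a curated structure database and GPU-scale
compute, so correctness is demonstrated on synthetic helical backbones:
C1′ atoms on a regular helix (rise 2.8 Å, twist 32.7°, radius 9.4 Å —
A-form-like distances, so the RBF ranges are exercised realistically), with
the C1′→N bond length (1.20/1.65/2.10/2.55 Å for A/C/G/U) and the axial
tilt of the C1′→C4′ bond (∓21°, ∓7°) carrying the base identity, plus
Gaussian jitter (default σ = 0.08 Å; the rule refuses configurations whose
signature separation is below 3σ).  A nearest-centroid classifier on the
per-nucleotide (bond length, tilt) features — with empirically calibrated
per-position-family centroids — gives the recovery ceiling (≥ 0.99; 1.00 at
the default noise).

The desk-scale reference experiment trains the default model on 500 such
backbones (lengths 20–40 nt) for 350 Adam steps at batch 16 and generates
with w = 1 for 50 held-out backbones: mean recovery ≈ 0.99 against the 0.25
random baseline.  The guidance sweep (8 samples per backbone, paired seeds)
shows recovery non-increasing and IntDiv non-decreasing along
w = 1.0 → 0.5 → 0.2.  These fixtures validate the machinery — feature
extraction, diffusion math, conditioning, guidance — not RNA physics: the
toy geometry has no base pairing, no secondary-structure variability, and a
perfectly regular backbone, so toy recovery says nothing quantitative about
recovery on experimental structures.

## Numerical choices and degenerate inputs

* Exact decode ties → alphabetically first letter; deterministic.
* σ_{t|s}² < 0 (invalid grid) raises; s → t collapses the step to S_t.
* Zero-length difference vectors in feature extraction raise a feature
  error naming the residue; terminal positions zero-pad undefined
  dihedrals/chain vectors rather than wrapping around.
* Alternate conformations: blank altloc wins, then occupancy (descending)
  with altloc letter as the final tie-break; model 1 only in multi-model
  files.
* All randomness flows through explicit `numpy.random.Generator` objects;
  identical seeds give bit-identical training curves and samples on CPU.

## Known limitations

* No pretrained weights; the published-corpus benchmark numbers are out of
  desk-scale reach and are not reproduced here.
* The unconditional branch shares the guided self-conditioning buffer
  during guided sampling (see above); alternatives are untested.
* The NumPy engine is single-threaded except inside BLAS; training beyond
  a few thousand steps or hidden sizes beyond ~256 becomes slow.
* In-silico folding validation of generated sequences (structure
  prediction, covariance-model scans) is outside this package's scope; the
  base-pair F1 here compares two given base-pair sets only.
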