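# ribodesign

Fixed-backbone RNA sequence design ("inverse folding") with a continuous
denoising diffusion model, for structural-bioinformatics and RNA-engineering
work: given the tertiary-structure backbone of an RNA chain, sample
sequences that are compatible with that geometry, with a tunable trade-off
between recovering the native sequence and exploring diverse candidates.

## The model

Each nucleotide is reduced to three atoms — C4′, C1′ and the glycosidic
nitrogen (N9 for A/G, N1 for C/U) — giving a backbone X ∈ R^(N×3×3).  The
sequence S ∈ {A,U,C,G}^N is one-hot encoded and relaxed to R^(N×4).  A
variance-preserving forward process corrupts it,

    q(S_t | S_0) = N(α_t S_0, σ_t² I),   t ∈ (0, 1],

with strictly decreasing SNR α_t²/σ_t².  A data-prediction network
d_θ(S_t, λ_t, X) — a GVP message-passing structure module over the k-NN
nucleotide graph cascaded into a Transformer with adaptive layer norm
conditioned on λ_t = log SNR(t) — is trained with the weighted objective
(α_t/σ_t)·‖d_θ − S_0‖², with stochastic self-conditioning (p = 0.5,
stop-gradient) and structure-condition dropout (p = 0.4).  Sampling runs
exact Gaussian ancestral steps from S ~ N(0, I) and decodes the terminal
predicted mean; classifier-free guidance mixes conditional and
unconditional predictions, w·d_cond + (1−w)·d_uncond, so lowering w below 1
trades sequence recovery for diversity (IntDiv).

Everything — including a small reverse-mode autodiff engine the network
runs on — is NumPy/SciPy-based and CPU-friendly.  Details, defaults, and
limitations: [docs/methods.md](docs/methods.md).

## Worked example

`examples/03_train_and_design.py` trains the default model on synthetic
helical backbones whose local geometry deterministically encodes the
sequence (so desk-scale training is possible without any database), then
designs sequences for held-out backbones:

```
loss curve: 123.88 -> 4.70 -> 7.04 -> 2.17 -> 0.64 -> 2.70
held-out recovery (w=1): mean 0.988 over 10 backbones
nearest-centroid oracle ceiling: 1.000
random-guess baseline: 0.25

native   ACAGCCUUGACCUGGGUGCCAAUUGAGCAGGAUCUCCAU
design 0 ACAGCCUUGACCUGGGUGCCAAUUGAGCAGGAUCUCCAU  (recovery 1.00)
design 1 ACAGCCUUGACCUGGGUGCCAAUUGAGCAGGAUCUCCAU  (recovery 1.00)
design 2 ACAGCCUUGACCUGGGUGCCAAUUGAGCAGGAUCUCCAU  (recovery 1.00)
```

The mean recovery (fraction of positions matching the native sequence) is
near the nearest-centroid ceiling computed directly from the toy geometry,
versus 0.25 for random guessing — the model has learned to read the
geometric code from the invariant features alone.  The other examples cover
backbone parsing and featurization, the diffusion math itself, the
recovery/diversity sweep over the guidance weight w, and metrics plus
cluster-based dataset splits.

A thin CLI mirrors the two shell-level tasks:

```bash
ribodesign extract --pdb structure.pdb --chain A --out backbone.npz
ribodesign design  --pdb structure.pdb --n 8 --w 0.5 --seed 7 \
                   --checkpoint model.npz --out designed.fa
```

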