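# Methods

## Problem setting

Imaging- and probe-based spatial transcriptomics (ST) measures expression in
situ with 2-D cell positions but covers a limited gene panel; dissociated
single-cell RNA-seq (SC) covers the transcriptome but loses position.
`stimpute` predicts, for every spatial cell, the expression of genes present
only in an SC reference. The only molecular correspondence between the two
assays is the set of genes both panels measure ("shared genes").

## Model

Eight multilayer perceptrons, trained in two stages.

**Autoencoders.** One encoder/decoder pair per domain compresses expression
into a domain-specific latent space: ST hidden widths 2048-1024-512 to a
256-dimensional latent, SC the same widths to a 512-dimensional latent;
decoders mirror (512-1024-2048). Every hidden block is linear → batch
normalization → LeakyReLU (negative slope 0.01) → dropout 0.2; output layers
are purely linear. Stage 1 trains each autoencoder independently on its own
domain's mean-squared reconstruction error (Adam, learning rate 1e-3, batch
512, 100 epochs by default); neither autoencoder ever sees the other
domain's data.

**Translators and discriminators.** Stage 2 freezes the autoencoders and
trains two latent translators, ST→SC (hidden 512-512-512-1024-1024) and
SC→ST (hidden 512-256-256-128-128), against two discriminators (hidden
256-128-128-64, one raw score per cell). The translator objective is

L_trans = λ_id · L_id + λ_cyc · L_cyc + λ_gan · L_gan,  λ = (1, 1, 0.1)

* **Cycle loss** — MSE between the original expression and the expression
  decoded after translating to the other latent space and back.
* **Identity loss** — one minus the Pearson correlation, computed per cell
  across shared genes, between translated-then-decoded expression and the
  source cell's measured expression, averaged over cells and summed over
  both directions. Only shared-gene output columns enter the computation,
  so its gradient with respect to every non-shared column is exactly zero:
  shared genes anchor translation while unmeasured genes stay free.
* **Adversarial loss** — the negated mean discriminator score of translated
  embeddings; discriminators train on a hinge loss (real above +1,
  translated below −1) with translated embeddings treated as constants.

Per step one discriminator update precedes one translator update
(translators at 1e-3, discriminators at 5e-4 to avoid overpowering).
Inference is deterministic: impute(x) = D_SC(T_ST→SC(E_ST(x))), eval mode,
floored at zero.

### Interpretation of the per-cell identity correlation

The identity correlation could also be read per gene across a batch. We use
the per-cell orientation because translation is a per-cell map and the loss
must be defined for arbitrary minibatches; a per-cell correlation is
batch-size independent. Cells where either shared-gene vector is constant
get correlation 0 (contributing loss 1), which penalizes degenerate constant
outputs without producing NaNs.

## Preprocessing

Applied to both matrices, in order: (1) drop genes with detection rate
(fraction of cells with a nonzero value) strictly below 0.05; (2) drop cells
with detection rate strictly below 0.1, removing ST coordinate rows in
lockstep; (3) for SC only, keep the 2,000 most variable genes — dispersion
(variance/mean) of log1p values, ties broken by gene name for determinism —
plus every shared gene, which the identity loss requires in the SC feature
space regardless of rank; (4) clip each feature at mean + 2 SD (population
SD, computed before the square-root step); (5) replace each value by its
square root as a mild variance-stabilizing transform. The shared-gene map is
rebuilt after every gene-set change. The pipeline is not idempotent
(clipping statistics change after the square root); it is defined on raw
counts only.

Gene identifiers are matched case-insensitively on symbols, with no
ortholog or alias resolution. Duplicate gene columns keep the copy with the
highest detection rate.

## Gene-holdout cross-validation

Shared genes are shuffled (seeded) and split into 5 near-equal disjoint
folds. Per fold, the held-out genes are removed from the ST matrix entirely
— they appear in no encoder input and no loss term, which an instrumented
audit asserts — a fresh model trains on the reduced ST matrix, and the fold
genes are predicted from the SC decoder's output and scored against their
measured ST values on the square-root scale (the model's supervision scale).
Every shared gene is scored exactly once.

The SC autoencoder is trained once per CV run and reused across folds: gene
holdout alters only ST columns, the SC matrix is identical in every fold, so
reuse cannot leak held-out information and saves roughly 40% of compute.
`run_cv(..., reuse_sc_autoencoder=False)` restores literal per-fold
retraining.

**Ablations.** The overlap ablation retains a nested 10/25/50/75/100% subset
of shared genes for training (dropped genes stay in the ST matrix as
ordinary, never-held-out columns) and re-runs CV on the retained set. The
sparsity ablation zeroes a seeded 0/25/50/75/90% sample of the raw ST
nonzero entries before preprocessing, then re-runs CV.

## Evaluation metrics

Per held-out gene, comparing measured (x) and predicted (x̂) per-cell
vectors: Pearson correlation (constant vectors score 0); SSIM on
min–max-normalized vectors with stabilizers C1 = 0.01, C2 = 0.03 (constant
vectors normalize to zeros); RMSE after independent z-scoring (population
SD, 1e-12 guard), making it affine-invariant; 1-D Wasserstein-1 distance
between the z-scored empirical distributions; Jensen–Shannon divergence with
base-2 logarithms (range [0, 1]) after normalizing each vector to a
probability distribution over cells, shifting by the global minimum first if
negatives occur and returning the maximal value 1 for zero-sum vectors.
Genes whose measured vector is identically zero are excluded and listed.

Diagnostics: Moran's I on a row-standardized 6-nearest-neighbor graph over
Euclidean coordinates (constant vectors score 0); ΔMoran's I =
I(imputed) − I(measured) per gene, summarized by median, mean and the
fraction within |ΔI| ≤ 0.10 — a check that imputation neither invents nor
destroys spatial structure. Note that on the synthetic regimes this shift
is substantially positive by construction: the generator's measured values
carry heavy Poisson/dropout noise (low autocorrelation), while imputation
recovers the smooth spatial latent, so a large positive ΔI there reflects
denoising toward the noiseless truth rather than fabricated spatial
patterns — the |ΔI| ≤ 0.10 band is meaningful on data whose measured noise
is mild; latent neighborhood recall under cosine
distance — the fraction of a cell's k = 15 original-space neighbors retained
among the m = 45 neighbors of its translated (one-way) or round-trip
translated (cycle) embedding. Clustering agreement uses ARI, NMI (arithmetic
normalization) and a cluster-averaged silhouette (per-sample scores averaged
within each identified cluster, then across clusters). Spatially-variable-
gene recovery is exposed as a generic AUPRC utility against an externally
supplied reference gene set; no SVG test is re-implemented here.

## Synthetic data generator

Both modalities share one rank-R factor model: per-gene loadings L (clipped
normal, scaled by 1/√R), per-gene baseline log-mean ~ N(0.7, 0.4), and
noiseless means exp(baseline + F·Lᵀ) — positive and right-skewed, which the
square-root step presumes. SC cells draw factors i.i.d. N(0, 1); ST cells
draw them from a spatially smooth field over uniform unit-square
coordinates, generated with 64 random Fourier features of a Gaussian kernel
(length scale `spatial_smoothness`, default 0.3) and standardized per
factor — linear in cell count where an exact Gaussian-process draw would be
quadratic.

Observation noise is modality-specific. Both: Poisson counting noise and
multiplicative log-normal amplification jitter (`noise_sd`, mean-corrected).
SC: log-normal library-size factors with coefficient of variation
`library_size_cv` and Bernoulli dropout (`sc_dropout`, default 0.3). ST:
additive Poisson optical background (rate 0.1 per entry) and heavier
zero-inflation via `st_dropout`. The ST panel is half of all genes (a fixed
design choice, configurable); a fraction `overlap_fraction` of it is also on
the SC panel, which otherwise contains every non-ST-exclusive gene.

The generator emulates: a shared low-dimensional biological program, partial
panel overlap, spatial smoothness, and count-like skewed noise. It does not
emulate discrete cell types, batch/FOV structure, platform-specific
chemistry, segmentation errors, or realistic gene–gene covariance beyond
rank R — so passing benchmarks here demonstrates that the machinery
recovers a planted shared latent under noise, not performance on any real
platform pair.

**Standard regimes.** `easy_regime`: 2000 ST / 3000 SC cells, 300 genes,
60% ST-panel overlap (90 shared genes after panel assignment), rank-8
latent, mild noise (`noise_sd` 0.1, dropout 0.2/0.3, library CV 0.3). This
is the benchmark condition for the recovery and diagnostic checks.
`hard_regime`: 10% overlap, 0.7 dropout in both modalities, `noise_sd` 0.3 —
the degradation condition.

## Numerical choices

* All network arithmetic is float32 (float64 available for gradient
  checks); analytic gradients are verified against finite differences.
* Batch normalization uses biased (population) variance for both
  normalization and running estimates (momentum 0.1, eps 1e-5); frozen
  networks always run in eval mode, so stage 2 leaves their weights and
  running statistics bit-identical.
* Weight initialization is fan-in-scaled uniform; one master seed fans out
  (via seed sequences) to initialization, batch samplers and dropout, making
  whole CV runs bit-reproducible on a fixed BLAS.
* An epoch in stage 2 is ceil(max(n_ST, n_SC)/batch) steps, with
  independent shuffled samplers cycling the smaller domain; partial batches
  of size ≥ 2 are kept, size-1 batches are dropped (batch statistics
  undefined).
* Discriminator output layers are linear; hinge margins act on raw scores.

## Problem sizes used by the shipped benchmarks

The test suite and the acceptance script run the full model (the layer
widths above are fixed) but scale the *data and epochs* to desk scale: the
recovery benchmark runs `easy_regime` with 30 autoencoder + 15 translator
epochs over 5 folds; the overlap/sparsity trend checks use a 400 ST /
600 SC-cell, 180-gene pair with 6 + 5 epochs and 3 folds, asserting only
the direction of each trend; determinism and leakage audits use
150-cell pairs. Epoch counts for the trend checks were fixed at values
where short training reliably learns on the small pair.

## Known limitations

* No GPU path, mixed precision, early stopping, or hyperparameter search;
  the single fixed architecture is used everywhere.
* No multi-sample/FOV batch structure, image channels, ambient-RNA or
  doublet handling.
* Uncertainty quantification for imputed values is out of scope.
* The identity loss requires a non-empty shared gene set; disjoint panels
  are detected early and refused at training time.
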