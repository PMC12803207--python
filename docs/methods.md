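# Methods

This note documents the model, objectives, simulator, and the numerical and
design choices behind `cellstack`. It is written for a reader who wants to
know exactly what the package computes and what its tests do and do not
establish.

## The generative model

A cell set is a matrix `X ∈ R^{K×G}` of UMI counts for K cells from one
biological sample over a shared gene index of size G. Each cell k is
represented by n gene-module tokens of width d; the flattened state
`Ē(k) ∈ R^{nd}` decodes to negative-binomial parameters through a cell-wise
map f:

    (ρ(k), θ(k)) = f(Ē(k)),      x_g(k) ~ NB(l_k · ρ_g(k), θ_g(k)),

where `l_k` is the observed library size (total counts; held fixed, not
learned), ρ(k) is a softmax-normalized rate vector and θ(k) > 0 a per-gene
inverse-overdispersion (variance μ + μ²/θ). The NB likelihood is evaluated
in a numerically guarded form (log1p-based) that stays stable for θ up to
about 1e6.

## Architecture

- **Input scale.** Counts are library-normalized per cell to the within-set
  median library size and log1p-transformed before tokenization. Masked
  genes are set to zero *after* normalization; no mask-indicator channel is
  added (the rectangular mask is shared across the set, so the model can
  infer maskedness from the all-zero column).
- **Tokenizer.** One linear layer (with bias) maps the G-vector to n·d
  values reshaped to n tokens of width d; a learned gene-token embedding
  `P ∈ R^{n×d}` is added. Query-role cells additionally receive the query
  position embedding `P_query ∈ R^{nd}` (reshaped to n×d) at this first
  embedding layer.
- **Tabular block.** Each of N_L blocks applies (1) intra-cell multi-head
  attention across the n tokens (feature width d), (2) inter-cell multi-head
  attention across the K cells with tokens flattened to nd (this is where
  the causal mask applies, and the sub-layer an ablation can disable), and
  (3) a token-wise feed-forward network with expansion factor 4 and GELU.
  Every sub-layer is post-norm: residual connection, then layer
  normalization (over d for the intra and FFN sub-layers, over nd for the
  inter sub-layer, matching each sub-layer's feature width).
- **Decoder.** A 2-layer GELU MLP (hidden width nd by default) maps `Ē(k)`
  to 2G outputs; ρ via softmax over genes, θ via softplus plus a 1e-4 floor.
- **Confidence classifier.** An MLP `R^{2nd} → R` scoring the concatenation
  of the mean prompt-condition embedding and a cell embedding; positive
  logits mean "more like a query cell". It always receives detached
  embeddings, so its gradients never touch the backbone.
- **Size presets.** Named presets span 3–9 layers and nd ∈ {800, 1600,
  3200} with n = 100 tokens and d ∈ {8, 16, 32}; tests and experiments use
  a much smaller configuration (2 layers, n = 8, d = 8, G ≤ 500) chosen so
  full training runs complete in minutes on one CPU.

The network, autograd, and optimizer are implemented directly on numpy in
float64 (`_autograd.py`, `nn.py`): reverse-mode automatic differentiation
over the exact operator set the model needs, and Adam with decoupled weight
decay, global-norm gradient clipping at 1.0, and warmup-plus-cosine learning
rates. Float64 keeps runs bit-reproducible for fixed seeds across platforms.

## Pretraining

Rectangular masked-gene reconstruction: per mini-batch a masking ratio is
drawn from U(0.1, 0.8), |M| = round(ratio·G) genes (at least one,
round-half-up) are masked identically across all cells of all sets in the
mini-batch, and the loss is

    L = L_recon + λ_SW · L_SW,    λ_SW = 0.01,

with L_recon the mean NB negative log-likelihood over the K×|M| masked
entries and L_SW the sliced Wasserstein-2 distance between a random subset
(size uniform on {32..128}, clamped to K) of the flattened cell embeddings
and a Gaussian prior with identity covariance centered on the subset mean.
Centering makes the regularizer invariant to set-level translations: it
shapes the distribution around the set mean and thereby encourages the
embedding to decompose into a set-constant plus a centered Gaussian — the
structure that makes latent factors linearly identifiable. Fresh prior draws
and 64 random projections are used per call; squared 1-D W2 distances of
sorted projections are averaged.

Validation uses a fixed mask ratio of 0.5 with a dedicated seed and reports
masked NLL plus the Pearson correlation between log1p predicted means and
log1p observed counts on masked entries.

## Post-training (alignment)

Starting from pretrained weights, an EMA teacher (decay 0.95, applied every
`update_interval` optimization steps; a copy of the student at step 0)
provides targets. Each training example is built from a prompt sample and a
query pool from a different context:

1. **Balancing.** Types above the per-type average count are downsampled to
   floor(average); the pool is then upsampled with replacement back to K.
   Only the first instance of a duplicated cell enters distributional
   losses.
2. **Ordering and partition.** Cells are ordered in randomized type blocks.
   The first round(0.25·K) cells are prompt-condition (used unchanged); the
   remaining positions split into prompt-context and query by a kept-ratio
   drawn from U(0, 1). Context cells are replaced by integer NB draws from
   the teacher's (μ, θ) for those cells (count-space resampling keeps the
   input space consistent). Query positions are filled with type-matched
   cells from the query pool; the displaced originals are the targets.
3. **Objective.** With a rectangular mask at ratio U(0.1, 0.3) and the
   causal attention mask (prompt-condition rows attend only within the
   prompt-condition block),

       L_FT = L_dist + λ_recon·L_recon + λ_SW·L_SW + λ_CLS·L_CLS,
       L_dist = 0.5·(L_gene + L_embed),

   all λ at their defaults (1, 0.01, 1). L_embed is the cell-type-stratified
   energy distance between student query embeddings and detached teacher
   embeddings at the same positions; L_gene is the energy distance between
   ZIN-sampled predicted expression and log-normalized target expression on
   the mini-batch's top (≤1000) Pearson-residual HVGs, using a shared
   dispersion equal to the median detached teacher θ over prompt cells;
   L_recon is masked reconstruction on prompt cells only; L_SW covers all
   cell embeddings; L_CLS is binary cross-entropy separating prompt-context
   (0) from query (1) cells. Types with fewer than 2 cells on either side
   are skipped in stratified losses. Gradients on the query position
   embedding and classifier are scaled ×10 (per-parameter multipliers, the
   equivalent of gradient hooks).

**ZIN sampler.** Energy distance on expression requires differentiable
samples. Per entry, with π = NB(0; μ, θ), the sample is zero with
probability π and otherwise a reparameterized Gaussian whose mixture mean
and variance match a third-order delta-method approximation of
E[log1p(s·X)] and Var[log1p(s·X)] for X ~ NB(μ, θ) (s is the per-cell
normalization scale). NB cumulants through κ4 enter; κ5/κ6 are dropped as
lower-order. The approximation is validated against an explicit NB
simulation oracle (within 2% on mean and variance at μ = 50). Non-positive
solved variances are clamped to 1e-6 and logged.

## Generation

Query cells start masked and carry their original expression (encoding cell
identity). For t = 0..T−1: assemble sets with 25% prompt-condition cells and
a prompt-context fraction rising linearly 0.2→0.4 (both sampled fresh from
the prompt pool each step), predict full expression for all query cells,
score each with the classifier against the mean prompt-condition embedding,
replace the lowest-logit masked cells until the masked fraction reaches
1−(t+1)/T, then re-mask every query cell with positive logit. Because the
replacement quota is derived from the schedule rather than the mask count,
the procedure terminates in exactly T steps for any classifier behavior;
re-masked cells keep their predictions until replaced again. Replacement
expression is the predicted NB mean l·ρ on the count scale (deterministic;
NB sampling available behind a flag); generated cells keep the query cell's
original library size. The post-hoc confidence filter keeps cells with
logit ≤ 2.5 (inclusive).

## Simulator

Counts follow the same NB decomposition the model assumes: per-gene log-rate
= cell-type log-mean + donor shift + condition log-fold-change, softmax
normalized per cell, scaled by a log-normal library size, with gene-wise
dispersions uniform on a configured range. Donor shifts are low-rank: genes
are partitioned into `module_count` modules and each donor draws one
N(0, donor_effect_sd) score per module, shared by all genes in the module.
This correlation structure is what makes sample identity inferable from any
gene subset — the property inter-cellular attention exploits — and it is the
structure the sliced-Wasserstein decomposition assumes (a per-sample
constant shift in expectation). Cell-type proportions are Dirichlet(α=2)
per sample, producing the imbalance that cell-type balancing corrects.
Perturbed genes are chosen uniformly per condition (condition 0 is an exact
null), with log-fold-changes N(0, perturbation_effect_sd); unperturbed
genes are exactly null so DE metrics have an unambiguous truth set.

Defaults describe a moderate cohort: 200 genes, 4 types, 6 donors, 2
conditions, 256 cells/sample, 10 modules, donor sd 0.5, perturbation sd 2.0
on 10% of genes, dispersions U(2, 20), library ~2000 (log-normal,
logmean 7.6, logsd 0.35). Experiments override these deliberately:

- **Context-benefit conditions**: 60 genes, one cell type, 30 two-gene
  modules, donor sd 2.0, library ~20 counts (logmean 3.0). At ~20 counts a
  masked gene's only module-mate carries well under one count per cell, so
  a single cell barely constrains its sample's module shifts while a
  128-cell ensemble pins them down - cross-cell pooling is the only good
  estimator. Training streams freshly simulated donors every round with one
  persistent optimizer and one global warmup-cosine schedule, removing any
  possibility of donor memorization. Validation scores a fixed probe subset
  of cells (present in every repetition-padded context) over 20 held-out
  donors: scoring different cells under different context sizes, or too few
  validation donors, otherwise adds composition variance larger than the
  effect being measured.
- **Identifiability probe**: per-set mean embeddings from 36 donors (768
  cells each, six sets of 128) are ridge-regressed onto the donors' module
  scores with donor-grouped train/test splits; the ridge strength is chosen
  by donor-grouped cross-validation on the training donors (the targets are
  30-dimensional, so an under-regularized probe is dominated by variance),
  and significance is judged against a donor-permutation null evaluated by
  the same procedure.
- **Recovery conditions**: 500 genes, 4 types, 10 donors × 2 conditions ×
  1000 cells (20k cells), one strong perturbation per cohort (sd 2.0 on 20%
  of genes so the recovery correlation is estimated over ~100 genes), donor
  sd 0.5, library ~1100. Both training stages stream freshly simulated
  cohorts — every round carries a new perturbation pattern and new donors —
  and post-training mixes perturbed and control prompts, so the only way to
  predict a held-out cohort's response is to read it from the prompt in
  context. Desk-scale experiment training uses no weight decay: with
  ~10^3-step budgets, decay pins small-utility readout weights (exactly the
  nascent cross-cell circuits) at zero; the full-scale training presets keep
  the conventional decay.

What the simulator does **not** emulate: pathway-level gene-gene structure
beyond modules, doublets, ambient RNA, batch chemistry, zero-inflation
beyond NB, cell-cycle or continuous states. Passing tests therefore show
the method's machinery works in the regime its assumptions describe; they
do not certify performance on real tissue atlases.

## Evaluation metrics

DE uses two-sided Wilcoxon rank-sum tests per gene on log1p
library-normalized expression (exact p for tie-free samples with n ≤ 25 per
side, normal approximation with tie and continuity correction otherwise;
constant genes on both sides get p = 1), Benjamini-Hochberg adjustment, and
significance = adjusted p < 0.05 with an optional |log2 LFC| floor
(0.25/0.5 exposed as flags). Log fold changes are differences of mean
log1p-normalized expression in log2 units. Metric operators (Pearson Delta
on absolute pseudobulk deltas, DE Spearman LFC, direction match, PR-AUC by
average precision, effect-size Spearman, top-N overlap/precision, Jaccard)
follow their standard definitions; degenerate inputs (no positives, empty
intersections, zero-variance deltas) report missing rather than a number.
Metric panels restrict genes to the top 2000 Pearson-residual HVGs of the
concatenated target and query counts; ties break by gene order.

Probes: the linear probe is per-cell-type logistic/ridge regression with
regularization chosen by donor-grouped 5-fold CV on 80% of donors, scored
on held-out donors with a per-donor test cap (default 2000 cells; balanced
accuracy or Pearson r). The MLP probe (one 128-unit ReLU hidden layer,
input standardization, L2 grid 0..1e-1 selected on validation loss, 70/15/15
donor split, early stopping with patience 12 over at most 80 epochs) is
built on scikit-learn's MLP estimators, which expose no dropout; the L2
grid is the regularization control instead.

## Numerical choices and degenerate inputs

- NB NLL: μ floored at 1e-10; lgamma gradients via digamma.
- Energy distance: V-statistic over all pairs; value-exact square roots with
  zero subgradient at exactly coincident points (so identical sets give
  exactly 0 and duplicated cells do not produce infinities).
- QC boundaries are inclusive (≥300 and ≤7000 detected genes, ≥700 UMIs);
  filtering everything warns and returns an empty set rather than erroring.
- Genes absent from a file relative to the unified index are zero-filled.
- Chunking keeps file-native cell order; chunks never cross files; residual
  cells are dropped.
- The mask always contains at least one gene; |M| uses round-half-up.
- Ties in generation-step logit ordering break by stable cell order; the
  per-step replacement quota is at least 1 while the schedule is positive.
- Checkpoints are npz archives with a JSON metadata block (version, config,
  gene index); loading verifies the version and all shapes.

## Known limitations

- Desk-scale only: the experiment protocols use two-layer models with
  nd = 64 and cohorts of tens of thousands of cells; no claim is made about
  behavior at foundation-model scale.
- In-context circuits form only sporadically at this scale. Direct
  context-shuffling probes show that most desk-scale pretraining runs never
  learn to pool information across cells (replacing a trained model's
  context with other donors' cells typically changes masked NLL by under
  1e-4 nats, against an information-theoretic ceiling near 0.5 nats), and
  post-training creates prompt *sensitivity* without directed transfer of
  the prompt's perturbation pattern. Individual trajectories that do acquire
  the circuit show the expected signatures (0.05 nats of context reliance,
  masked NLL improving with unique context cells), so the machinery is
  correct but the emergence is a rare event at ~10^3 optimizer steps. The
  corresponding end-to-end expectations are encoded, unweakened, in the
  test suite; the context-benefit and perturbation-recovery runs measure
  and report exactly this shortfall.
- The ZIN moment matching is an approximation; it is validated against a
  Monte-Carlo oracle in one regime, not proven accurate everywhere.
- The MLP probe has no dropout (see above).
- Generation replaces expression with NB means by default; sampling mode
  exists but is not used by the evaluation protocols.
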