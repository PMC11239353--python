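# Methods

`fcdecode` implements a complete functional-connectivity decoding pipeline
for naturalistic (movie-watching) fMRI at the region-of-interest level:
synthetic BOLD cohorts, FC/ISFC connectivity features, a spectral
graph-convolutional classifier of cognitive state (Theory-of-Mind vs Pain),
a convolutional variational autoencoder that predicts false-belief task
performance group from connectivity, Shapley-value attribution, and the
validation protocols. This note documents the models, the generator's
assumptions, the tunable parameters, and the numerical choices.

## The synthetic cohort generator

Real data for this paradigm is a 155-subject developmental cohort (122
children aged 3–12, 33 adults) who watched a 5.6-minute silent animated
film; twelve spherical ROIs (six in the ToM network: bilateral TPJ, PCC,
vmPFC, dmPFC, precuneus; six in the pain network: bilateral MFG, anterior
insula, secondary somatosensory cortex) yield 168 time points (TR = 2 s)
across ten high-activation event windows, five ToM and five pain. The
generator emulates the statistical structure these analyses rely on without
any imaging data.

For subject *s*, window *w* of state σ(w) ∈ {ToM, Pain}, the ROI signal is

    x_s(t) = a·m_age(s)·S_w(t) + b·I_s(t) + c·ε(t)

- **S_w** — stimulus-evoked component: multivariate normal with a
  state-dependent correlation matrix Σ_S^σ, drawn once per window and
  **shared by all subjects**. Default Σ_S^σ is two-block compound-symmetric:
  0.9 within the engaged network, 0.1 within the other, 0.05 between.
- **I_s** — intrinsic component, subject-specific. Its correlation matrix is
  two-block with the ToM↔Pain block set analytically so that the *observed*
  between-network correlation of the mixture equals the subject's
  performance-group coupling target (defaults: pass 0.8, inconsistent 0.5,
  fail 0.2). The within-network level is raised just far enough above the
  compound-symmetry PSD bound to keep the matrix valid. The solved matrix is
  then jittered twice through Wishart resampling — once per subject
  (df = 60) and once per window (df = 30) — so intrinsic coupling is
  non-stationary. This non-stationarity is what separates FC from ISFC:
  FC absorbs it, the leave-one-out inter-subject average does not.
- **ε** — white measurement noise.

Default mixture weights are (a, b, c) = (0.40, 1.00, 0.20): a
stimulus-driven variance share of ≈ 13%, intrinsic ≈ 84%. `m_age` is a
stimulus-weight multiplier of 0.55 for the youngest (3–4 yr) children
(44 of the 122), modelling their weaker stimulus-locked responses; all
other groups use 1.0. Child performance groups default to 84 pass /
23 inconsistent / 15 fail; adults are untested on the task and carry a
placeholder "pass" label, and are excluded from performance prediction.

Per-window lengths are not individually published (only the 168-point total
and the >8 s floor), so the default schedule uses {17,17,17,17,16} TRs per
network, interleaved. Age and performance group are assigned independently.

What the generator does **not** model: haemodynamic response shapes, head
motion, physiological noise, spatial structure within ROIs, and — notably —
group differences in the *stimulus-locked* response. Because group coupling
is planted in the intrinsic component, ISFC (which suppresses intrinsic
coupling by construction) carries no group information here, and
performance prediction is run on FC. On real data, where group differences
are partly stimulus-locked, ISFC-based prediction can outperform FC; results
on this generator say nothing about that contrast.

## Connectivity features

FC is the Pearson correlation of window-restricted, column-z-scored ROI
signals. ISFC correlates subject *s*'s ROI *i* with the mean over all other
subjects of ROI *j* (leave-one-out), then symmetrizes as (M + Mᵀ)/2; it is
computed per window, one matrix per subject per window. Group means average
through the Fisher z-transform with |r| clipped at 1 − 10⁻⁷. Edge-level
inference is a one-sample t-test of Fisher-z values per edge with
Benjamini–Hochberg FDR across the N(N−1)/2 unique edges (α = 0.01 default);
an edge constant across subjects is flagged degenerate and survives when
nonzero. Edges are labelled strong / moderate / weak around the 0.5
landmark with a configurable ±0.05 "≈ 0.5" band.

## The graph-convolutional state decoder

Each subject × window sample becomes a graph: adjacency |r| with zero
diagonal (a "positive" clipping mode is available), normalized Laplacian
L = I − D^{−1/2} A D^{−1/2}, and the rescaled operator
L̃ = (2/λ_max)L − I with λ_max from an exact symmetric eigensolve (a
λ_max ≈ 2 shortcut exists for larger graphs). Filtering uses the Chebyshev
recurrence T_k = 2 L̃ T_{k−1} − T_{k−2}; equivalence with direct
spectral-domain filtering U g(Λ̃) Uᵀ x is pinned to 1e−8 in tests.

Node features concatenate ten catalog statistics of the node's window
time-series (mean, variance, skewness, kurtosis, autocorrelations at lags
1–3, energy, absolute sum of changes, linear-trend slope) with the node's
connectivity profile (its matrix row); columns are z-scored across samples
(a label-free transform). A FRESH-style relevance filter (Mann–Whitney U
per feature, Benjamini–Yekutieli FDR) and node2vec/walklets random-walk
embeddings (numpy skip-gram with negative sampling) are available as
alternative node-feature sources.

The decoder stacks 1–3 blocks of: Chebyshev graph convolution (order
K = 3 default, per-node bias) → batch normalization → ReLU → pairwise node
max-pooling (nodes merged in ROI-table order; the coarsened graph sums edge
weights over merged pairs) → dropout. Filter schedules are [16], [16, 32],
[16, 32, 64] for depths 1/2/3. The flattened node features feed a dense
softmax layer. Training: Adam, learning rate 0.001, dropout 0.65, weight
decay ρ = 0, batch size 32, up to 100 epochs, cross-entropy loss with an
optional (ρ/2N_P)‖W‖² term, early stopping on a 10% stratified validation
split with patience 3. Because the validation loss is noisy at this data
size, the patience rule only activates after `min_epochs` = 40; without
that floor roughly a third of runs stopped half-trained. Probability ties
at prediction resolve to the lower class index. Everything is
deterministic under the configured seed (named SHA-256-keyed substreams).

## The convolutional VAE and the latent performance classifier

The encoder maps an N×N connectivity matrix (N ∈ {12, 8, 6}; inputs
rescaled from [−1, 1] to [0, 1]) through two 3×3 stride-2 SAME
convolutions (32 → 64 filters), a 32-unit dense ReLU layer, and two linear
heads μ(x), log σ²(x) for a 32-dimensional Gaussian posterior. The decoder
mirrors it (dense → reshape → two transposed convolutions → sigmoid
output). For N = 12 the parameter counts are 39,392 (encoder) and 74,689
(decoder), asserted per layer in the tests; for N = 8 and 6 the spatial
algebra is recomputed (8→4→2, 6→3→2).

Training maximizes the ELBO with Adam (lr 0.001, batch 128, 50 epochs):
per-sample squared reconstruction error summed over matrix entries plus the
closed-form Gaussian KL. Two standard optimization guards prevent posterior
collapse, which otherwise occurs for some initializations on these
low-variance inputs: the KL weight ramps linearly from 0 to 1 over the
first 10 epochs, and a free-bits floor of 0.05 nats per latent dimension
removes the KL gradient from dimensions below it. The reported `vae_loss`
diagnostic is per-entry MSE plus the KL term.

Group prediction follows the printed protocol exactly: a dense head with
three sigmoid outputs on the latent means, one-hot binary cross-entropy,
Adam, 50 epochs; the predicted group is the argmax with ties resolving to
the lowest index in (pass, inconsistent, fail) order. The VAE is trained on
per-subject-per-window matrices (10 per child, 1220 total), and held-out
subjects are classified by averaging the head's scores over their ten
windows. Latent inputs are standardized; dimensions with near-zero variance
are left unscaled.

## Shapley attribution

Exact Shapley values enumerate all 2ⁿ subsets (n ≤ 16) with the
|S|!(n−|S|−1)!/n! weights; the sampled estimator averages marginals over
random permutations and reports per-feature standard errors. Absent
features are imputed with a background (training-mean) matrix; attribution
runs at ROI granularity (masking all edges incident to a region, 12
features, exact) or edge granularity (66 features, sampled). ROI ranking
takes the median |φ| per region across attributed samples, mapping edge
features to both endpoints; ties keep ROI-table order. The explained output
is the model's probability for its predicted class. "Dominant" regions are
the top three per network.

## Validation protocols

All splits are subject-level: the ten windows of a subject never straddle a
split. One caveat is inherent to ISFC: the leave-one-out group mean that
defines a subject's ISFC matrix is computed over the whole cohort, so
held-out subjects' raw signals contribute (weakly, as 1/(N−1) of an
average) to training subjects' features. This mirrors how ISFC is defined
and used in practice; the state labels themselves never cross the split.
Repeated 80:20 uses ⌊0.8N⌋ training subjects (124/31 at N = 155),
10 independent shuffles, stratified when labels are supplied; five-fold CV
partitions subjects into disjoint folds; leave-one-out holds out one
subject. Metrics (accuracy, per-class and macro precision/recall/F1,
confusion matrices, one-vs-rest ROC/PR curves) come from scikit-learn.

## Problem sizes used in the shipped checks

The automated checks run the full 155-subject cohort: state decoding over
10 repeated 80:20 splits per feature set (1,550 graph samples each), the
permuted-label control, the VAE pipeline over 5 splits of the 122 children
(1,220 matrices), spectral equivalence on 200 random graphs (N ≤ 12,
K ≤ 5), and 500-replicate nulls for the FDR machinery. These sizes were
chosen to keep the whole suite at desk scale while leaving the statistical
conclusions stable across seeds.

## Known limitations

- The generator's group signal is intrinsic-only (see above): it validates
  the machinery, not the real-data claim that ISFC predicts performance
  better than FC.
- Subjects within a group share the same target coupling; real cohorts
  have within-group heterogeneity beyond the Wishart jitter used here.
- The numpy networks are exact but not fast: they are sized for 12-node
  graphs and 12×12 matrices, not whole-brain parcellations.
- MVPA / LSTM / CNN / decision-tree / SVM comparators are deliberately out
  of scope; standard library implementations can be slotted into the same
  split plans for comparison.
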