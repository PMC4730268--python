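# Methods

This note documents the models and procedures implemented in `lpqppi`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that affect results.

## Sequence encoding: the property response matrix

A protein of length N with per-position property values v₁…v_N (from a
20-residue scalar scale; the packaged default is a hydrophobicity index) is
encoded as the outer-sum matrix `PRM(i,j) = vᵢ + vⱼ`. The matrix is
symmetric by construction and every entry lies in
[2·min(scale), 2·max(scale)].

* **Ambiguous residues.** The default policy maps B → mean(N, D),
  Z → mean(Q, E), J → mean(I, L) and any other non-canonical letter (X, U,
  O, …) to the mean of all 20 values; a `strict` policy rejects them with
  the offending letter and position. Rationale: deterministic, keeps
  sequences rather than discarding them.
* **Compression.** Matrices with side > 250 are resized to exactly 250×250
  by separable bilinear interpolation over a uniform grid (configurable to
  nearest-neighbour). Bilinear resizing is convex and separable with
  identical row/column weights, so symmetry is preserved to roundoff and
  the value range never widens. Descriptors are computed on the compressed
  matrix.
* **Length bounds.** Proteins shorter than 50 residues are filtered out
  before featurization, together with every pair touching them; an upper
  bound (default 5000 residues, configurable) bounds the N×N memory of the
  uncompressed matrix before resizing.

## The LPQ descriptor

At each position x of the matrix the short-term Fourier transform over an
m×m neighbourhood (default m = 3, the smallest valid window) is

    F(u, x) = Σ_{y ∈ N_m×m} f(x − y) · exp(−j 2π uᵀ y),

evaluated at the four canonical frequencies u ∈ {(a,0), (0,a), (a,a),
(a,−a)} with a = 1/m — the lowest non-zero frequencies satisfying the
blur-positivity condition. The 8 real components [Re u₁..₄, Im u₁..₄] are
quantized by sign into one byte per position (bit k set iff component k is
positive), and the descriptor is the normalized 256-bin histogram of the
codes. Pair features concatenate two descriptors (512 numbers summing
to 2).

Numerical and design choices:

* **Quantization of zeros.** Components are compared against a
  scale-relative dead zone (10⁻⁹ × the matrix's maximum magnitude) rather
  than a strict `> 0`: the kernels are zero-mean, so analytically-zero
  responses (constant regions, and see below) come out of the convolution
  as ±10⁻¹⁶ roundoff, which must deterministically quantize to bit 0 —
  otherwise roundoff noise masquerades as texture.
* **Outer-sum degeneracy.** For any outer-sum matrix v ⊕ v the responses
  at the two diagonal frequencies (a,a) and (a,−a) factorize into terms
  each containing a zero-sum geometric factor and are therefore exactly
  zero. PR-matrix code maps consequently occupy only 16 of the 256 bins:
  the effective descriptor is the outer product of a 4-state sign
  distribution of the 1-D profile's windowed DFT (local peak-ness and
  local slope signs) with itself. The 256-bin histogram is kept for
  generality — other matrix-valued encodings populate all bins.
* **Borders.** Only "valid" positions (window fully inside) are coded by
  default; a zero-padding mode is available. Padding invents content at
  the boundary, so it is off by default.
* **Whitening.** The classic decorrelation of the 8 responses under a
  first-order Markov image model (pixel correlation ρ = 0.9, SVD-based
  orthogonal transform) is implemented behind a flag and off by default;
  the default quantizes the raw responses.
* **Blur invariance.** The sign pattern is invariant to centrally
  symmetric blur only in the ideal infinite-window case. With the 3×3
  default the approximation requires a spatially correlated input: for a
  smoothed random field the histogram intersection after a 5×5 Gaussian
  (σ = 1) blur is ≈ 0.90, while for an i.i.d.-noise field — whose energy
  sits at frequencies outside the small-window regime — it drops to
  ≈ 0.58. The property suite therefore demonstrates blur robustness on a
  correlated field.

## Rotation Forest

For each of the L trees: the n features are randomly split into K disjoint
subsets of nominal size M = ⌈n/K⌉ (the last subset may be smaller; its
missing slots are conceptually zero-features and carry zero coefficients);
for each subset, ⌈0.6·N⌉ sample rows are drawn without replacement (with
replacement available), mean-centered, and all M PCA coefficient vectors
are kept as an orthonormal block; the blocks are assembled into a sparse
block-diagonal rotation aligned with the original feature order, and a
CART decision tree (Gini, unpruned by default) is fitted on X·R. The
ensemble averages tree probabilities; exact 0.5 ties go to +1.

* The 3/5 draw is **without** replacement by default: drawing 60% with
  replacement would contain duplicates and fewer unique rows than the
  fraction suggests.
* Rows are drawn across both classes; no per-block class subsampling.
* All M components are retained (full rotation); centering only, no
  variance scaling.
* Eigenvector signs are canonicalized (largest-|entry| positive) and a
  rank-0 draw (all rows identical) falls back to an identity block with a
  logged warning, so training is fully reproducible.
* Randomness: one master seed; per-tree substreams are spawned from it so
  that growing L never reshuffles earlier trees. The tree learner's own
  seed is drawn from the same substream.

## Evaluation

Standard confusion-matrix metrics (accuracy, sensitivity, precision, MCC)
with +1 = interacting; any metric with a zero denominator is reported as 0
and flagged with a warning rather than aborting a degenerate fold. ROC
curves sweep all distinct score thresholds (ties grouped) with the
positive-class ensemble probability as the score; AUC uses the trapezoid
rule. Cross-validation is stratified with seeded shuffling (so fold class
balance matches the overall balance) and reports per-fold rows plus
mean ± sample (n−1) standard deviation. Sequence-identity redundancy
filtering of datasets is deliberately out of scope — it is curation that
requires all-vs-all alignment, not part of the predictor.

## Synthetic study conditions

The generator emulates a balanced binary interaction benchmark: 60
proteins of 50–150 residues drawn i.i.d. with uniform residue usage, and
600 pairs at a 50/50 class balance (defaults; all configurable). For a
pair (a, b) with mean hydrophobicities m_a, m_b the interaction propensity
is

    s = σ( β · (m_a·m_b − τ) / σ_pop ),      β = 6,

where τ and σ_pop are the population median and standard deviation of the
products over all candidate pairs. Labels are +1 with probability
(1−ε)·s + ε·(1−s), ε = 0.1 by default; pairs are drawn (each unordered
pair used at most once) until the positive fraction is met exactly.

The argument of the sigmoid is standardized deliberately: under i.i.d.
residue sampling the mean hydrophobicity of a ≥50-residue protein varies
only by sampling noise (sd ≈ 0.085 about a mean of ≈ 1.0), so an
unstandardized β·(product − τ) would spread only ≈ ±0.7 and the labels
would be near coin flips — the Bayes-optimal AUC of such labels is ≈ 0.65
regardless of classifier. Standardizing makes β a scale-free effect size:
β = 6 yields strongly informative labels behind the ε flip noise (Bayes
AUC ≈ 0.9) and turns the dataset into a usable positive control.

What the generator does **not** emulate: interactome topology (hubs,
degree heterogeneity), domain-level interaction interfaces, homologous
sequence families, or realistic residue composition differences between
proteins. A pass on this benchmark shows the pipeline can recover a
planted composition-level signal end-to-end; it is not evidence about
accuracy on real interactomes.

Benchmark protocol: because a single stratified fold assignment carries
roughly ±0.02 of AUC noise at 600 pairs, benchmark quantities (the
planted-rule CV AUC, the ε = 0.5 no-signal control, and the ensemble-size
monotonicity check) are averaged over five fold-assignment seeds on the
fixed dataset. At the default conditions the pipeline (K = 8, L = 20)
reaches mean CV AUC ≈ 0.78 versus a label ceiling of ≈ 0.88, and the
no-signal control sits at 0.50 ± 0.02. The descriptor's outer-sum
degeneracy (16 effective bins, above) is the main loss relative to the
ceiling: the planted mean-level signal reaches the classifier only through
the sign statistics of local profile shape, and CV accuracy at these
conditions is ≈ 0.70.

## Parameter sweep

The two-phase grid procedure fixes L = 20 and scans K, then fixes the best
K and scans L; ties break toward the smaller (cheaper) parameter value,
and failed cells are recorded in the trace without aborting the sweep.
Sensible grids for the 512-feature representation are K ∈ {10, …, 70} and
L ∈ {10, …, 70} in steps of 5.

## Problem sizes

Default test and acceptance runs use the synthetic conditions above (60
proteins, 600 pairs, 512 features, 5 folds, L = 20), for which a full
cross-validation completes in well under a minute on one CPU; oracle
comparisons (direct STFT evaluation, Mann–Whitney concordance) run on
matrices ≤ 15×15 and 300 scored points respectively, where the O(n²)
references are exact and fast.
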