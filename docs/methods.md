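# Methods

This note documents the models implemented in `m6afuzzy`, the parameters
that matter, the synthetic data the test-suite runs on, and the numerical
and design choices made where the design was genuinely open.

## Problem setting

Input data are fixed-length RNA windows (default 41 nt) centred on a
candidate modification site — an adenosine for m6A, shared by positives and
negatives — with binary labels.  The package learns a scoring function for
such windows and evaluates it by class-stratified cross-validation or by
training on one dataset and testing on another.

## Position-specific k-mer propensity encoding

For k-mer order k (default 5) and window length L, each class's training
sequences yield per-position relative frequencies F(m, j) of k-mer m
starting at position j (each sequence contributes exactly one k-mer per
position, so every frequency column sums to 1).  The default propensity is
the class difference

    score(m, j) = F⁺(m, j) − F⁻(m, j),

so each table column sums to 0 and a k-mer unseen in both classes scores
exactly 0.  A positives-only variant (`propensity_mode="positive"`) is
available because the frequency-difference convention, while standard for
position-specific propensity encodings, is one of two reasonable readings;
the difference form is the default since the class contrast is what carries
the signal.  An optional additive pseudocount (default 0) smooths the
frequencies without breaking the column-sum identities; the zero default
keeps the all-zero-table identity (identical class multisets ⇒ zero
features) exact.

Encoding is a pure lookup: window position j contributes the propensity of
the window's own k-mer at j, giving d = L − k + 1 features (37 for the
canonical 41/5 setting).

**Feature standardization.**  Encoded features are z-scored per column with
training-split statistics (`standardize`, default on).  This is not
cosmetic: the fuzzy design mixes O(1) intercept columns with raw propensity
columns two orders of magnitude smaller inside each rule block, and the
block prior assigns one scale γ_i to the whole block.  Without
standardization the misscaled blocks are pruned wholesale and held-out
performance collapses at moderate sample sizes; with it the same problems
are fit stably.  The scaler is part of the model file, so prediction is
self-contained.

## TSK fuzzy system

A first-order TSK system with K rules (default 25 — a mid-range choice for
~40-dimensional inputs; the rule count is a free parameter and is echoed
into every report) computes

    y(x) = Σ_k μ̃_k(x) (p₀ᵏ + Σ_j p_jᵏ x_j).

Per-feature Gaussian memberships use exp(−(x_j − c_jᵏ)²/δ_jᵏ) — the width
δ, not δ², in the denominator and no factor ½.  Rule firing strengths are
products over d features, accumulated in the log domain with per-row max
subtraction so that no sample can underflow to an all-zero rule row even at
large d.

Antecedents come from fuzzy c-means (fuzziness m = 2, the standard choice;
tolerance 1e−6 on the maximum centre shift; at most 300 iterations;
centres initialized as K distinct seeded-sampled rows of the training
features).  FCM iterations weight by μ_ikᵐ as usual, while the antecedent
centre/width estimates use the unexponentiated memberships

    c_jᵏ = Σ_i μ_ik x_ij / Σ_i μ_ik,
    δ_jᵏ = h · Σ_i μ_ik (x_ij − c_jᵏ)² / Σ_i μ_ik,

with the width scale h (default 1, exposed as `--fuzzy-h`).  Widths are
floored at 1e−8·var_j + 1e−12 so a cluster collapsing onto a constant
feature keeps the membership defined.

Fixing the antecedents makes the output linear in the consequents: sample i
lifts to x_gi = (μ̃₁(x_i)(1, x_i), …, μ̃_K(x_i)(1, x_i)), one (1+d)-sized
block per rule.  The intercept columns of any row sum to 1 (firing-strength
normalization), a standing unit test.

## Block-sparse Bayesian learning

Classification is handled as regression of the ±1 labels on the fuzzy
design (threshold 0; a score of exactly 0 maps to −1).  Each rule's block
p_i gets the prior N(0, γ_i B_i); hyperparameters are estimated by type-II
maximum likelihood with the fixed-point updates

    γ_i = Tr[B_i⁻¹(Σ_i + μ_iμ_iᵀ)]/d_i,
    B_i = (Σ_i + μ_iμ_iᵀ)/γ_i,
    β  = N / (‖y − X_gμ‖² + Tr[ΣX_gᵀX_g]),

initialized at γ_i = 1, B_i = I and β₀ = 0.01‖y‖² (the literal signal-energy
rule; since ‖y‖² = N for ±1 labels this is 0.01·N — dimensionally unusual
for a noise precision, so an inverse-variance alternative
β₀ = 1/(0.01·var y) is selectable via `beta_init_rule`).  The loop stops
when ‖γ_new − γ‖/‖γ‖ ≤ η (default 1e−4) or after `max_iter` (default 500),
in which case the model is returned flagged not-converged.

**Correlation constraint.**  The raw B_i update estimates a d_i×d_i matrix
from one block's statistics and overfits.  By default the updated blocks
are pooled: each is normalized to unit mean diagonal, a single first-order
correlation r = (pooled first off-diagonal)/(pooled diagonal) is extracted,
clipped into (−0.99, 0.99), and every B_i is replaced by the Toeplitz
matrix [r^{|s−t|}] of its size — the standard constraint in the
block-sparse Bayesian literature.  `correlation_constraint` also offers
"unit-scaled" (per-block diagonal rescaling only) and "none" (the literal
update, useful for oracle tests; with it the cost trace is non-increasing
on well-posed problems, while the Toeplitz projection can raise it by tiny
amounts — cost increases beyond 1e−6 are logged, not asserted, since the
printed β update carries no monotonicity guarantee).

**Pruning.**  Blocks with γ_i < 0.01·max_j γ_j are clamped to 0 and leave
the working set.  The threshold is deliberately coarse: at finite SNR the
fixed point leaves switched-off blocks on a small nonzero γ plateau
(empirically 1e−4–4e−4 of the largest γ on the reference generator), so a
much smaller threshold never fires; 0.01 sits about two orders of magnitude
above that plateau and the same distance below the smallest genuinely
active block scale, and matches common practice in reference BSBL-EM
implementations.

**Posterior computation.**  Σ = (Γ⁻¹ + βX_gᵀX_g)⁻¹ and μ = βΣX_gᵀy are
evaluated in the primal form when the active width is ≤ N and through the
Woodbury/dual form C = β⁻¹I + X_gΓX_gᵀ otherwise; the two agree to 1e−8
(tested).  All factorizations are symmetric-PD Cholesky with a 1e−10
diagonal jitter retry, logged.  β is capped at 1e10: in the interpolating
regime (active width > N) the fixed-point β diverges and the cap keeps C
numerically positive-definite without affecting non-degenerate fits.

**Ablation variants.**  `fit_sbl` runs the identical machinery with
all-singleton blocks (B_i degenerates to the scalar 1 and
γ_i = Σ_ii + μ_i²); it is bit-identical to `fit_bsbl` under a singleton
block map.  `fit_ls` is the classical penalized TSK baseline
p = (XᵀX + λI)⁻¹Xᵀy with a fixed ridge constant (default λ = 1); λ = 0 on
a rank-deficient design falls back to the minimum-norm solution, logged.
No regularization constant is exposed on the Bayesian fits — the point of
the method is that the equivalent quantity is learned.

**Probabilities.**  The Gaussian predictive distribution gives
sd = √(x_gΣx_gᵀ + 1/β) and probability Φ(score/sd) — an interpretation of
"posterior probability output" that follows directly from the model; it is
a calibration convenience, not part of the decision rule.

## Evaluation protocol

SN, SP, ACC, MCC (0 when a denominator factor vanishes, logged) and AUC by
the Mann-Whitney rank statistic with ½ credit for ties (identical to the
trapezoidal ROC area; cross-checked in tests against an O(N²) pairwise
oracle and scikit-learn).  Cross-validation uses class-stratified folds
with seeded shuffling; per fold, the propensity table, the scaler, the FCM
antecedents and the consequent fit see the training split only — corrupting
a fold's test sequences provably leaves that fold's trained table hash
unchanged (tested).  Fold metrics are macro-averaged by default (micro
pooling by flag); whether reported per-dataset numbers in this field are macro or micro
aggregates is generally unstated, and macro matches per-fold reporting.

## Synthetic data

`gen_block_sparse` samples exactly the generative model the prior assumes:
i.i.d. standard-normal design, k_active of M blocks drawn from
N(0, Toeplitz(r)), noise rescaled so the realized SNR equals the request
exactly.  It provides ground truth for support-recovery and ablation
checks (at N = 150, M = 20, blocks of 4, r = 0.9, 25 dB: exact support
recovery in 48/50 seeds with < 2.4% coefficient error, and median held-out
AUC ordering BSBL ≥ SBL ≥ ridge).

`gen_motif_dataset` emulates the statistical structure reported for
tissue-specific m6A benchmarks: both classes centre on an adenosine
(position 21 of 41); positives carry a GGACA consensus at positions 19–23
with per-position fidelity and GC-rich flanks, negatives AU-rich
background flanks (background P(G)=P(C)=gc/2, P(A)=P(U)=(1−gc)/2).
Presets: **strong** (fidelity 0.95, GC 0.60 vs 0.35 — a clearly separable
regime mirroring the pronounced consensus/flank contrast reported for real
benchmarks), **moderate** (0.75, 0.55 vs 0.45), **null** (no motif, no GC
contrast — a negative control).  What the generator does *not* emulate:
transcript context, sequence redundancy/homology structure, secondary
structure, position-dependent background composition, and label noise.
Passing the synthetic end-to-end checks therefore demonstrates that the
pipeline recovers the kind of positional k-mer signal these benchmarks are
reported to contain, not that it attains any particular accuracy on real
data.

## Problem sizes in the test-suite

The acceptance-level checks run at the sizes stated above for the
block-sparse generator, and at 1000+1000 sequences for the end-to-end
5-fold CV of the strong and null presets (mean ACC 0.95, AUC 0.99, and
chance-level AUC respectively, at the defaults).  Unit tests use smaller
instances of the same generators.

## Known limitations

- The decision threshold is fixed at score 0; at small training sizes the
  regression-on-labels formulation can leave the score distribution offset
  so that ranking quality (AUC) is high while SN/SP are imbalanced.
  Threshold calibration on a validation split would mitigate this and is
  out of scope here.
- The Toeplitz correlation pooling assumes one shared first-order
  correlation across all rule blocks; it is a regularization device, not a
  model of the true within-block covariance.
- FCM with duplicate feature rows can produce tied rule centres (logged);
  duplicate rules are harmless but wasteful.
- Runtime is dominated by the per-iteration Cholesky of the active-block
  posterior; dense designs wider than ~2000 columns are slow on one core.
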