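# Methods

## Model

A bulk expression profile of heterogeneous tissue is modeled as a
non-negative linear mixture of cell-type expression signatures:

    M = G C,        M ∈ R≥0^{m×n},  G ∈ R≥0^{m×k},  C ∈ Δ^{k×n}

where m is the number of genes, n the number of samples, k the number of
cell types present, and each column of C lies on the probability simplex
(per-sample proportions summing to one).  The user supplies a candidate
panel L of k_init ≥ k purified reference signatures, possibly from other
studies, possibly including cell types absent from the mixture.  The task
is blind: k, the identities, G and C are all estimated.

Identifiability requires k_init < n; the pipeline refuses otherwise.
Proportions are only well defined relative to a normalization of the
signature columns; `blindmix` works throughout with signatures scaled to
a common column total (sum one inside the factorization), which matches
how controlled mixtures are actually produced (equal total RNA input per
sample).

## Algorithm

**Normalization.**  After restricting mixture and panel to their shared
genes (mixture gene order), both are jointly quantile-normalized: all
columns pooled, every column mapped onto the mean sorted profile, ties
receiving the mean of the reference values at the tied positions.  Each
matrix's columns are then rescaled so every column sums to the mean of
that matrix's column sums.  The phrase "each column sums to its mean" is
ambiguous in isolation; scaling to the mean of the column sums is the
only reading with a normalizing effect, and is what is implemented.
Inputs on a log scale are exponentiated first (`unlog_base`), since the
mixture model is additive in linear intensities.

**Factorization.**  W is initialized from the column-normalized panel
(exact zeros floored at δ = 1e-12, since multiplicative updates cannot
leave zero); H from seeded uniform(0,1) draws.  Updates are the standard
multiplicative rules for the Frobenius objective,

    H ← H ⊙ (WᵀM) ⊘ (WᵀWH + δ)
    W ← W ⊙ (MHᵀ) ⊘ (WHHᵀ + δ)

followed each iteration by rescaling W's columns to sum one with the
compensating inverse rescale of H's rows, which leaves the product WH
(hence the objective) unchanged.  The iteration stops at `nmf_max_iter`
(default 2000) or when the relative objective change drops below
`nmf_tol` (default 1e-6).  The objective is monotone non-increasing to
numerical tolerance; the test-suite asserts this per iteration.

**Determination.**  Signatures are compared with the symmetric
Kullback–Leibler divergence on probability-normalized vectors, floored
at `epsilon` (default 1e-12) and renormalized so zeros cannot produce
infinities:

    SKLD(p, q) = Σ_i (p_i − q_i)(ln p_i − ln q_i) = KL(p‖q) + KL(q‖p)

Natural logarithm, no ÷2.  Each reference maps to its nearest factor
column; the distinct winners are the estimated cell types (k̂ = their
count).  When several references share a winner, the closest one names
the column and the others are dropped — together with factors nobody
claims, this is the mechanism that rejects decoy candidates.  Exact ties
break to the lower column index (winners) and lower panel index
(labels), making the whole procedure deterministic.

**Classes and voting.**  Assignment runs label-wise first; afterwards
chosen columns whose winning labels share a user-declared class are
averaged into one column named by the class.  The restart r of
`n_runs` uses seed `base_seed + r`; a label is retained when its
selection fraction is ≥ `majority_threshold` (default 0.70, read as
inclusive: 7 wins suffice at 10 runs — the natural-language "more than"
would demand 8 of 10 for a 70% threshold, which no 10-run setup could
express exactly).  A retained label's final signature is the entry-wise
mean over the runs that chose it, renormalized to sum one.  If nothing
survives the vote, an explicit "no cell types identified" error suggests
lowering the threshold or revising the panel.

**Proportions.**  Each (normalized) mixture column is regressed on the
consensus signatures by Lawson–Hanson NNLS and the weights divided by
their sum.  The fit runs in the same normalized space the signatures
were learned in, so residual norms are meaningful.  The per-sample (not
per-cell-type) normalization is the only direction under which the
result "represents cell-type proportions".

## Parameters

| parameter            | default | meaning |
|----------------------|---------|---------|
| `majority_threshold` | 0.70    | fraction of restarts a cell type must win |
| `n_runs`             | 10      | random restarts voted over |
| `nmf_max_iter`       | 2000    | iteration cap per restart |
| `nmf_tol`            | 1e-6    | relative objective change at which to stop |
| `epsilon`            | 1e-12   | SKLD probability floor |
| `unlog_base`         | none    | exponentiate inputs first (2 for log2 data) |
| `quantile_normalize` | true    | joint quantile normalization of mixture+panel |

Similar panels (e.g. immune subsets) benefit from more restarts and a
lower threshold; well-separated tissues converge with fewer.

## Synthetic benchmark generator

The generator emulates the controlled-mixture experiments used to
validate deconvolution methods: known cell types mixed in known
proportions, observed through an over-complete panel.

* **Signatures** are exponentiated Gaussian profiles: per-gene baseline
  log-expression ~ N(6, 1) shared across types, per-type deviation sd
  0.3 (inter-type log-scale correlation ≈ 0.92, typical of real tissue
  transcriptomes), and a 20% fraction of marker genes elevated by 1.5
  natural-log units (≈ 4.5-fold) in their own type and suppressed by 0.5
  elsewhere.  All signature columns are scaled to a common total.
* **Decoys** — candidates not present in the mixture — are drawn from
  the same family but, as with real tissue panels, are related to the
  mixture's cell types: each decoy's deviation profile correlates 0.7
  with a "sibling" true type and expresses the sibling's markers at 70%
  of the full contrast.  This relatedness is not a convenience: the
  determination step rejects a decoy only when its reference ends up
  closer to a true-claimed factor than to its own drifted factor column,
  which is exactly the geometry real panels (e.g. intestine as a decoy
  beside liver) provide.  Panels of mutually near-orthogonal signatures
  defeat the mechanism — each decoy reference simply re-claims the
  factor column it initialized — and are also unlike any real tissue
  panel.
* **Proportions** are symmetric Dirichlet draws (concentration 1.0,
  i.e. uniform on the simplex — a broad design including near-pure
  samples).
* **Noise** is multiplicative log-normal, applied elementwise: sd 0.05
  on the mixture (measurement noise) and sd 0.1 on the panel copies of
  the true signatures ("off-study" references).  Multiplicative noise is
  scale-dependent and keeps everything non-negative without clipping.

The standard regime is 500 genes, 3 true types, 3 decoys, 30 samples.
What the generator does **not** emulate: probe-level artifacts, batch
effects, platform-specific intensity distributions, and systematic
(correlated) cross-study reference bias.  The last point matters when
interpreting baseline comparisons: with only unstructured reference
noise, plain NNLS against the panel remains fairly strong, whereas real
cross-study references degrade it far more.  Passing tests therefore
demonstrate the mechanics and relative ordering of the methods, not the
absolute error levels to expect on real cross-platform data.

## Numerical choices and degenerate inputs

* δ = 1e-12 guards denominators and floors initial zeros of W.
* The objective-monotonicity contract allows relative slack 1e-10 per
  iteration for floating-point noise.
* Duplicate gene rows collapse by arithmetic mean at load time; negative
  or non-numeric cells are rejected with their position named.
* All-zero columns (normalization), zero-sum signatures (SKLD), zero
  total NNLS weight (proportions) raise errors naming the offender.
* A single-reference panel is legal and yields k̂ = 1 with unit
  proportions.  k_init ≥ n raises an identifiability error.  If every
  candidate is retained (k̂ = k_init) a warning notes the panel may be
  under-specified — a cell type missing from the panel cannot be
  detected.
* Full determinism: run r uses seed base+r; identical inputs and seed
  give bit-identical results, including the CLI's output files (the run
  log carries no timestamps).

## Design notes and limitations

* **Quantile normalization trades bias for comparability.**  Forcing
  every column onto a common distribution removes cross-study scale
  effects but also flattens genuine compositional differences between
  samples; on noiseless synthetic data this is the dominant error source
  (several percent in the proportions), and recovery tightens when the
  step is disabled (`quantile_normalize=False`) for data already on a
  common scale.  The default keeps it on, because panels are typically
  from other studies.
* **NMF non-uniqueness.**  Without sufficiently distinct (marker-rich)
  signatures, the factorization has rotational ambiguity and recovered
  factors need not match the truth even at zero reconstruction error;
  reference initialization and voting mitigate but cannot remove this.
* The NMF update rule is the standard multiplicative scheme for the
  Frobenius objective; alternatives (KL-divergence NMF, sparsity terms)
  are out of scope.
* Proportion estimates carry no uncertainty quantification.
* The evaluation module matches labels by exact name and scores
  class-level estimates against the sum of member proportions; reported
  ± values are population standard deviations over per-(cell type,
  sample) absolute errors.
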