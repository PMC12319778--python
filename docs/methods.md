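# Methods

## Decomposition

The PLS correlation decomposes `C = X_zᵀ Y_z / (n − 1) = U Σ Vᵀ`, where
`X_z`, `Y_z` are the columnwise z-scored blocks. The n − 1 denominator is
used both in z-scoring and in `C`, so entries of `C` are exact Pearson
correlations (the two conventions must match; with mixed denominators the
entries would be scaled by n/(n−1)).

All k = min(p, q) latent variables are always returned, even when `C` is
numerically rank-deficient (e.g. n − 1 < k): trailing near-zero singular
values keep the LV count fixed, which the permutation bookkeeping relies
on. Tied singular values keep LAPACK's order and are not individually
identifiable.

SVD signs are arbitrary; each LV is flipped so that the largest-magnitude
element of its `V` column is positive. This fixes reproducible output and
has no effect on any reported metric (null values are norms, stability uses
|r|, bootstrap alignment absorbs reflections).

Validation: blocks must be finite, share n ≥ 3 rows, and contain no
constant column (z-scoring is undefined there; the error names the
offending feature). Constancy is detected by exact range (`ptp == 0`), not
by a variance threshold, so near-constant but informative columns pass.

## Permutation inference

Per permutation instance the rows of one block are shuffled and the
decomposition repeated. One pseudorandom table of shuffle indices (n_perm
rows, each a permutation of 0..n−1) is generated from the seed before any
test runs and is consumed by all four methods, making cross-method p-value
differences attributable to the rotation alone.

Shuffling X's rows by a permutation π re-pairs observations identically to
shuffling Y's rows by π⁻¹. The brain method therefore applies the inverse
of each shared index row to X, so all four methods score the *same*
permuted decomposition per instance. This is what makes the following
exact, per instance, rather than merely distributional:

* conservation — `Σᵢ valᵢ² = Σᵢ σ(p)ᵢ²` (R orthogonal, V(p) orthonormal);
* LV1 dominance — `valᵢ ≤ σ(p)₁`, hence with shared indices every rotated
  method's LV1 p-value is ≤ the unrotated one on every dataset;
* k = 1 collapse — with a single behaviour column all four tests coincide.

The rotation solves the orthogonal Procrustes problem
`min_R ‖V(p) R − V‖_F` via `V(p)ᵀ V = N O Pᵀ`, `R = N Pᵀ`; the transform
is `V(p) (Σ(p) R)` — row i of R scaled by σ(p)ᵢ before the
left-multiplication — and null values are the column L2 norms. Since V(p)
has orthonormal columns these norms equal the column norms of `Σ(p) R`,
which the vectorised implementation uses; a test pins the batched path to
the explicit one-instance route. The "both" method averages the U-side
and V-side value vectors computed on the same Y-shuffled decomposition.

p-values are the literal proportion `count(null ≥ observed) / n_perm`,
with ties counted as exceedances (conservative). An opt-in
`(count+1)/(n_perm+1)` estimator guarantees strict validity. Singular
values below 1e-12 are treated as zero in the comparison so float noise on
rank-deficient problems cannot register as exceedances. Identity
permutations drawn by chance are kept; rejecting them would bias the null
(for n ≥ 10 the probability is negligible anyway).

Permutations are processed in chunks sized to bound the (n_perm × n × q)
intermediate at ~160 MB, with batched LAPACK SVDs; this is what keeps
paper-scale runs (10,000 permutations) and the simulation sweeps
tractable.

## Split-half stability

Each split partitions the rows into two disjoint halves (odd n: the first
half gets the extra row; no stratification), PLS runs on each half, and
for each LV the absolute Pearson correlation between the halves' singular
vectors is recorded per block. Absolute values absorb arbitrary SVD signs.
LVs are matched across halves by rank order only — deliberately *not* by
Procrustes, which is reserved for bootstrap alignment; rank matching is
the stability metric's definition, and rotating here would mask exactly
the instability the metric is meant to expose. Splits that draw a constant
column (possible with discrete features) are redrawn with a retry cap.
Summaries report per-LV mean and SD over splits; both are stored so either
can be plotted.

## Bootstrap reliability

Observations are resampled with replacement; per resample the
decomposition is recomputed and a Procrustes rotation aligning the
resampled brain component `U(b)` to the original `U` is applied to both
weight matrices before accumulation. Rotation is justified here, unlike in
permutation testing: a bootstrap sample contains the same latent effects,
possibly reordered or reflected, so alignment maps them back. Bootstrap
ratios are mean aligned weight over its SD across resamples (z-score
analogue); an SD below 1e-12 is flagged and the ratio capped rather than
divided through. Behavioural loadings are Pearson correlations of each Y
variable with the Y latent scores on the original sample; their 95%
intervals are 2.5/97.5 percentiles of the within-resample (aligned)
loadings — percentile rather than BCa, as nothing finer is claimed, and
computed on aligned scores so the interval describes the same LV as the
point estimate.

## Synthetic data

The null regime draws both blocks iid N(0, 1) with no cross-block
structure. The latent regime assembles a joint correlation matrix with one
encoded effect: a uniformly random unit-vector pair (a, b) in the whitened
spaces and `C_XY = C_XX^{1/2} a r bᵀ C_YY^{1/2}`, giving first population
canonical correlation exactly r with no other pair constrained.

Within-block structure defaults to the identity. This is a deliberate
simplification of generators that impose decaying within-block spectra: it
keeps the embedded canonical correlation analytically exact (verified to
1e-8 against an independent generalized-eigenvalue routine) and leaves the
cross-block effect — the quantity every conclusion here rests on —
unchanged. An optional `powerlaw` mode supplies random-axis power-law
eigenvalue decay; converting the resulting joint covariance back to unit
diagonals is a per-variable rescaling, to which canonical correlations are
invariant, so the embedded r survives exactly there too. What identity
mode does *not* emulate: correlated within-block features and principal
axes partially aligned with the effect, both present in real imaging data.
Passing tests therefore demonstrate the rotation mechanism and the
metrics' sensitivity under clean conditions, not performance under
realistic within-block covariance.

Noise is added after sampling and before z-scoring, as iid N(0, sd²) on
both blocks; on unit-variance data an sd of 1 doubles variances and
attenuates every pairwise correlation by half.

Defaults mirror the reproduced simulation designs: p = 90, q = 10, one
latent effect, r = 0.3, n = 1000 for the strength/noise sweeps; grids of
10 sample sizes log-spaced 10–10,000, 10 canonical correlations linearly
spaced 0.1–0.9, 10 noise SDs linearly spaced 0–1.

## Sweeps

`run_analysis` crosses a grid with replicates: per cell it generates a
dataset, runs all four permutation tests on shared indices, and computes
split-half stability once (it is method-independent). Replicate seeds are
spawned from the master seed via `SeedSequence`, so results are
bit-identical regardless of worker count. Failed replicates are recorded
and the sweep aborts past a 1% failure fraction. Two profiles are bundled:
`desk` (20 replicates, 1000 permutations, 20 splits) for interactive runs
and `paper` (100 / 10,000 / 100) for the full design. Pass rates use
strict `p < α`.

## Numerical and statistical choices in the tests

The simulation-driven checks run at reduced scale chosen as the smallest
that leaves the qualitative contrasts unambiguous: 500 null datasets at
n = 100 with 1000 permutations for type-I calibration; 20 replicates with
500 permutations for the sample-size trend; 20 replicates with 20 splits
for the strength/noise trends. Stochastic trend assertions compare
consecutive grid means with an allowance of two combined Monte-Carlo
standard errors — on the flat low-n segment of the pass-rate and stability
curves the true means are at the noise floor, and a strict inequality
between two noisy estimates of equal means would be a coin flip, not a
test of the trend.

The strength-versus-sample-size trend is asserted for n ≥ 100 only: below
n ≈ p the leading covariance-explained share of an essentially random
cross-correlation matrix is inflated (measured here: mean ≈ 0.32 at
n = 10 versus ≈ 0.19 at n = 100 for 90 × 10 at r = 0.3), so LV1 strength
genuinely falls before it climbs; monotonicity is a property of the
n > p regime.

## Known limitations

* Exchangeability-block or Freedman–Lane permutation schemes are out of
  scope, as are set-based (sum-of-covariance) alternatives to per-LV
  testing.
* The generator encodes exactly one latent effect (m = 1); multi-effect
  designs are not supported.
* Identity within-block structure understates the difficulty of real data
  (see above); the `powerlaw` mode is a partial remedy, not a calibrated
  model of any imaging modality.
* Bootstrap loading intervals are percentile-based and computed after
  alignment; with very unstable LVs alignment itself is noisy and the
  intervals should be read as descriptive.
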