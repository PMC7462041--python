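# Methods

## The model

`serkit` treats an IDP conformational ensemble as a three-parameter
probability density p(R_g, δ, R_e) over per-conformation descriptors and
summarizes it by plug-in Shannon entropies of its binned one- and
two-parameter marginals, arranged in the symmetric 3×3 ensemble entropy
matrix S_ens (row/column order R_g, δ, R_e). The dissimilarity between
two SERs is the root of the sum of squared **upper-triangle** elements
(j ≥ i, six terms) of Δ_AB = S_ens,A − S_ens,B. Note the six-term sum is
*not* the nine-term full-matrix Frobenius norm of the symmetric Δ: the
flat-limit-vs-zero comparison at n = 4 gives 5.369 under the six-term
convention and ≈ 7.20 under the nine-term one. serkit implements the
six-term convention; the anchor value 5.369 is asserted in the test suite
so a drift to the other convention cannot pass.

Key assumptions:

* The ensemble is given (simulated elsewhere or generated synthetically);
  serkit performs no conformational sampling of real force fields.
* Frames are treated as exchangeable draws; no autocorrelation correction
  is applied (entropies are invariant to row order by construction).
* Entropies are plug-in estimates of the binned distribution. No
  bias correction (Miller–Madow etc.) is applied: the quantity of interest
  is the binned-histogram entropy itself, whose flat-limit bounds
  (ln n, 2 ln n) are exact, not an estimate of a continuous differential
  entropy.

## Descriptors

* Gyration tensor T = Σ wᵢ (rᵢ − r̄)(rᵢ − r̄)ᵀ / Σ wᵢ, uniform weights by
  default (every atom counts equally; "mass" weighting is an explicit
  per-atom weight vector). trace(T) = R_g² exactly.
* δ = 1 − 3(λ₁λ₂+λ₁λ₃+λ₂λ₃)/(λ₁+λ₂+λ₃)², per conformation from that
  conformation's eigenvalues (a distribution p(δ) requires per-frame
  values; ensemble-averaged tensor invariants would not give one).
  Eigenvalues from `numpy.linalg.eigvalsh`; round-off negatives below
  1e-12 of the leading eigenvalue are clamped to 0. δ of a coincident
  point set (zero trace) is an error; a rank-1 (collinear) tensor gives
  exactly 1.
* R_e uses one atom in the first and one in the last residue. Default
  selection: Cα when the labels contain any "CA", otherwise the first atom
  of the first residue and the last atom of the last. An explicit label
  that resolves to zero or several atoms per end is an error, never a
  guess.
* Cross-length comparisons divide R_g and R_e by √N (ideal-chain scaling)
  before binning; δ is dimensionless and untouched. The normalized flag
  travels with the series and double normalization is refused.

## Binning — the central reproducibility decision

* n = 4 bins per axis by default (the regime in which the flat-limit
  bounds 1.386/2.773/5.369 are stated); configurable.
* Equal-width bins, half-open [eᵢ, eᵢ₊₁) with the last bin closed
  (numpy histogram convention; bit-reproducible).
* δ ranges over [0, 1] by theory. R_g/R_e ranges are either explicit or
  "pooled": [min, max] over *all* series entering one comparison, padded
  by a relative 1e-9. Pooled-by-default matters: per-sequence ranges would
  silently erase mean shifts and conflate range changes with shape
  changes. Values outside an explicit range are clipped into the edge
  bins (logged) so Σp = 1 always.
* Every resolved binning carries a fingerprint (SHA-256 over n and the
  edges). Difference/dissimilarity operations refuse matrices whose
  fingerprints differ — the most likely silent-misuse mode is comparing
  matrices binned on different grids, and it is made structurally
  impossible rather than documented away. The same edges feed the 1-D and
  2-D marginals, which guarantees max(s(X), s(Y)) ≤ s(X,Y) ≤ s(X)+s(Y).

## Sequence-side conventions

* FCR/NCPR use {D, E} negative and {K, R} positive; histidine is excluded
  by default (mostly neutral at pH 7) and can be opted in.
* Alignment distance is the p-distance on a *consumed* alignment:
  gap-vs-residue columns count as differences, both-gap columns are
  excluded from the denominator. This is the simplest defensible rule; any
  externally computed distance matrix can be supplied as TSV instead.
* Quadrant analysis thresholds normalized (max = 1) sequence and SER
  distances at 0.5 over unordered pairs; pairs exactly on the threshold
  fall in the "low" class. Inputs whose maximum is not 1 (±1e-9) are
  rejected rather than silently rescaled.

## Clustering

Average linkage (UPGMA) by default — the conventional choice for
similarity trees — with single/complete available; the linkage method is
recorded in outputs. Ids are sorted lexicographically before linkage so
scipy's index-order tie-breaking becomes a documented, permutation-stable
rule. Exported Newick trees use the ultrametric convention height =
merge-D/2, so the path length between two leaves equals the D at which
they join; labels that are not plain alphanumerics are single-quoted.

## Synthetic generators

Two independent tiers so descriptor code and entropy code are separately
testable:

1. **Coordinate tier** — a correlated random walk: bond directions
   d_k ∝ g·d_{k−1} + (1−g)·u_k with u_k uniform on the sphere, scaled by
   the bond length (default 3.8 Å, the Cα–Cα virtual bond). g = 0 is the
   freely jointed chain with exact closed forms ⟨R_e²⟩ = (N−1)b²,
   ⟨R_e²⟩/⟨R_g²⟩ → 6, used as the oracle; larger g stiffens the walk.
   Optional confinement rejects frames whose maximal centroid distance
   exceeds a radius; acceptance below 0.1% within the attempt budget is an
   error rather than a hang.
2. **Property tier** — (R_g, δ, R_e) rows drawn from stated marginals
   joined by a Gaussian copula (correlation scalar or full PSD matrix).
   This gives exact control over what the entropy matrix sees: coupling
   changes move only the off-diagonal entries while every marginal — and
   hence every ensemble mean — stays fixed. That reproduces, in miniature,
   the central phenomenon that first moments can mask ensemble
   differences.

What the generators do *not* emulate: excluded volume, sequence-specific
interactions, any real force field. Passing tests therefore demonstrate
the correctness of the measures and the pipeline, not the thermodynamic
accuracy of any ensemble.

Every sampler takes one integer seed and uses a single local
`numpy.random.Generator`; identical parameters and seed reproduce outputs
bit for bit.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately small problem
sizes that still pin the statistics: 5000 frames of an N = 200 chain for
the ideal-chain closed forms (5% tolerance), 50k–60k copula rows for
entropy saturation and coupling contrasts, 200 random matrix triples for
metric axioms, 1000 random grids for entropy inequalities, 5-item
instances against the naive O(m³) UPGMA oracle. Tolerances: 1e-10 to
1e-12 for algebraic identities, 1e-9 for rigid-motion invariance, sampling
tolerances as stated per test.

## Known limitations

* The three-parameter joint entropy s(R_g, δ, R_e) is intentionally not
  computed; the method decomposes into marginals only.
* No null model/significance for D values; D is descriptive.
* PDB reading interprets only MODEL/ENDMDL, ATOM, TER (HETATM and
  non-blank/'A' altlocs are skipped with a warning) — simulation outputs
  are clean, robustness over completeness.
* Binary trajectory formats (DCD/XTC) are out of scope; the TSV property
  table is the canonical interchange, so any analysis stack can feed the
  entropy stage.
* κ (charge patterning) is carried as metadata only; it is not computed
  here.
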