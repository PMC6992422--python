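# Methods

## The model

`srdca` infers a generalized Potts model over aligned sequences
s = (s₁ … s_L), s_i ∈ {1 … q},

    P(s) ∝ exp( Σ_i h_i(s_i) + Σ_{i<j} J_ij(s_i, s_j) ),

from a multiple sequence alignment.  The partition function is never
computed: parameters are estimated by minimizing the weighted,
L2-regularized negative pseudo-log-likelihood

    ℓ_PL = −(1/B_eff) Σ_b ω_b Σ_i log P(s_i^b | s_\i^b)
           + λ_h Σ ‖h_i‖² + λ_J Σ ‖J_ij‖²,

where the site conditional is the softmax over q states of
h_i(a) + Σ_{j≠i} J_ij(a, s_j^b), ω_b ≥ 0 is the per-sequence weight and
B_eff = Σ_b ω_b.  The *asymmetric* variant is used: each site's
conditional is an independent multinomial logistic regression, and the
two directed estimates of each coupling block are averaged afterwards.
Contact scores are Frobenius norms of the coupling blocks taken over the
non-gap states after shifting each block to the zero-sum gauge, followed
by the average-product correction (APC)

    S̃_ij = S_ij − S_i·S_·j / S_·· ,

with row/column/total means over off-diagonal entries (the formula does
not fix the convention; the off-diagonal choice is asserted against a
literal implementation in the tests).

## Subfamily reweighting (SR)

Given K labeled subfamilies, every sequence of subfamily k receives the
common weight ω_k, the vector (ω₁ … ω_K) is swept over a regular grid on
the unit simplex (all compositions of 1/step, vertices included), and a
weighted DCA is run at each grid point.  Per-pair score surfaces
S̃_ij(ω) are condensed by the multilinear kernel

    φ_k(ω) = ω_k · Π_{i≠k} (1 − ω_i),      F_ijk = Σ_ω φ_k(ω)(S̃_ij(ω) − ⟨S̃_ij⟩),

with ⟨·⟩ the unweighted mean over (non-skipped) grid points, which makes
F invariant to per-pair constant shifts.  φ_k is 1 at vertex k and 0 at
every other vertex; the product form generalizes the K=3 definition to
arbitrary K.  argmax_k F_ijk assigns contact (i, j) to a subfamily;
whole interfaces are summarized by the mean of S̃_ij(ω) over their pairs
per grid point (exportable in barycentric coordinates for triangle
plots).

Because rows with zero weight are dropped before optimization, the scan
slice at a vertex is *bit-identical* to a plain DCA run on that
subfamily's rows alone, and multiplying all weights by a constant
changes nothing beyond floating-point round-off (both properties are
tested).

## Parameters and defaults

| parameter | default | notes |
|---|---|---|
| λ_h, λ_J | 0.01, 0.01 | customary asymmetric pseudo-likelihood defaults; the reference implementation's exact values are not recoverable |
| optimizer | L-BFGS, zero start | per-site gradient tolerance 1e−5, ≤500 iterations; deterministic |
| identity filter | 0.9 | greedy first-kept-wins pass; identity over all columns, gap–gap counting as a match |
| contact threshold | 5 Å | strict heavy-atom distance, keeps nearby homodimer interfaces disjoint |
| sequence separation | \|i−j\| ≥ 5 | ranking eligibility for all precision metrics |
| grid step | 0.05 (CLI), 0.25 (benchmark tests) | 0.01 (5151 points for K=3) reproduces the original resolution but costs ~350 fits more |
| `OPTIMIZER_SCORE_TOL` | 1e−4 | documented per-score reproducibility bound between numerically equivalent fits |

Score ranking breaks ties lexicographically by (i, j).  Gap states
participate in inference (21-state model) but never in scoring.

## Synthetic benchmark

The generator emulates a family whose subfamilies share a fold but carry
distinct homo-dimerization interfaces: K Potts models share random
fields (scale 0.3) and coupling blocks on shared "fold" pairs, and each
subfamily adds blocks on its own "interface" pairs; all blocks are
random zero-sum-gauge matrices scaled to a target Frobenius norm, so
planted strength is directly comparable to fitted scores.  Sequences are
drawn by vectorized single-site Gibbs sampling (independent chains, 100
burn-in + 25 recorded sweeps by default), validated against exact
enumeration on an L=3, q=2 model.

Defaults: L=30, q=8, K=3, 500 sequences per subfamily, 6 shared and 3
specific pairs per subfamily (all at separation ≥ 5), coupling strength
3.0 for both categories.  q=8 rather than 21 keeps a full simplex scan
in the minutes range; q is configurable to 21 for fidelity runs.  The
strength 3.0 (per-entry RMS ≈ 0.38) was chosen so that a subfamily's own
500 sequences rank all nine of its planted pairs at the very top of the
APC ranking while 100 sequences sit at the edge of detectability — the
data-scarcity contrast between large and small subfamilies that
motivates reweighting in the first place.  Unequal subfamily sizes
(e.g. 500/100/500) probe exactly that regime; note that at only three
gradeable pairs per realization, recovery rates there swing widely
between seeds, so conclusions should always be averaged over several
replicates.

What the generator does **not** emulate: phylogenetic correlation
(sequences are i.i.d. within a subfamily — defensible after identity
pre-filtering, but real alignments retain tree structure), gaps and
alignment errors, length variation, and subfamily-specific conservation.
The last point matters for two derived analyses: because all subfamily
models share their fields, single-site marginals are nearly identical
across subfamilies, so mean pairwise identity and PCA projections show
essentially no subfamily structure on this benchmark (expected pairwise
identity is a pure marginal statistic).  The subfamily signature lives
in the pairwise column statistics instead, and the tests assert it
there (per-subfamily mutual information on planted pair columns).  Real
families additionally separate by conservation, which is why the PCA
cluster test uses field-differing models.

Passing tests on this benchmark therefore demonstrate that the
machinery — weighted inference, kernel integration, assignment — behaves
as designed under controlled covariation, not that any particular real
family will yield the same accuracy.

## Structure handling

Contact maps use a strict "any heavy-atom pair < 5 Å" rule; intra-chain
and inter-chain contacts are kept apart, inter contacts are pooled over
all chain pairs of the declared biological assembly (homodimer copies
share one index space), and self-pairs (i, i) are recorded but never
credited by metrics.  Chains map onto alignment columns by global
pairwise alignment (BLOSUM62, gap open −11 / extend −1, free end gaps)
against the per-column majority-residue consensus, with a 30% identity
floor.  The family reference combines the intra-molecular union across
structures with per-structure interfaces defined as inter contacts not
explained intra-molecularly anywhere — an inter pair that is an intra
contact in any structure cannot evidence a subfamily-specific interface.
Interface pairs that fall inside the excluded near-diagonal band
(separation < 5) are reported but can never be credited; this is a
documented limitation of separation-filtered ranking.

## Numerical choices and degenerate inputs

* Per-site regressions are convex; L-BFGS from a zero start with a fixed
  gradient tolerance makes fits deterministic on one platform.
  Scans with identical configuration and seed are bit-reproducible.
* All-identical columns are handled by the L2 penalty (no crash; the
  column's couplings shrink to ~0).
* An all-zero score matrix passes through APC unchanged with a warning.
* Simplex grid points where every sequence would get weight zero are
  skipped with a warning recorded in scan metadata and excluded from
  kernel means; under the documented preconditions (every subfamily
  non-empty) this cannot occur.
* A benchmark written to FASTA and re-read is treated as a 21-state
  protein alignment; unused states carry no data and their couplings
  vanish under regularization, so scores are equivalent, at ~3× the fit
  cost of the native q=8 representation.

## Problem sizes used in tests

The default test benchmark (1500 sequences, L=30, q=8, 15-point grid)
keeps one full SR scan near 15 s and the whole suite in a few minutes;
the grid-refinement check re-runs the scan at 45 points.  These sizes
are the package's own test-scale choices; the CLI accepts the original
resolution (step 0.01) for real analyses.

## Known limitations

* The identity filter is O(B²L); for very deep alignments a dedicated
  clustering tool is the right choice upstream.
* Kernel scoring is restricted to the multilinear family; the interface
  is a proof of principle, not an optimized scoring function.
* Subfamily labels are inputs; no automatic subfamily discovery.
* No mean-field/MCMC DCA variants, no GPU path, no mutational-scan
  energetics.
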