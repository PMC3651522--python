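# Methods

This note documents the models, conventions and design choices behind
phyloblot, in the order data flows through the pipeline.

## Densitometry normalization

Input is one row per gel lane: gel id, lane, species, organ, target band
intensity and loading-control (β-actin) intensity, all in arbitrary
densitometry units. Normalization is two-stage:

1. **Loading-control ratio.** Each lane's target intensity is divided by
   its control intensity, on the assumption that actin abundance is
   comparable across species within a tissue. Control intensities must be
   strictly positive; a zero target band is retained as a ratio of 0 at
   this stage but any species whose *mean* level is non-positive is
   excluded (with a logged drop reason) before log-scale analysis.
2. **Cross-gel rescaling.** Each gel's ratios are multiplied by
   (grand mean of reference-species lanes across gels) / (mean of that
   gel's reference lanes). The per-gel reference statistic is the *mean*
   of reference lanes rather than a single lane, because gels may carry
   more than one reference lane. The global anchor is the grand mean, so
   when gels are comparable the adjustment is close to 1. Any positive
   anchor would do: it cancels in log-scale correlations, so r², F, t and
   p downstream are invariant to the choice.

Actin normalization precedes cross-gel rescaling. With that order the
cross-gel factor is a pure gel effect; the reverse order would mix lane
loading into the gel factor.

Species summaries are the arithmetic mean, sample standard deviation
(n − 1 denominator) and replicate count of the rescaled lanes. Species
with zero lanes for an organ are absent from that organ's analysis, never
zero-filled.

**Linear-range QC.** For a serial-dilution series the widest contiguous
run of ≥ 3 points whose intensities fit a through-origin line within a
relative tolerance (default 10%) is reported as the assay's linear region.
The tolerance is a package default: the procedure is a QC gate, not a
correction, and the default reproduces the qualitative behavior expected
of film densitometry (saturation above, noise below the linear region).

## Statistical conventions

- All traits are log-transformed (base 10 by default; the base does not
  affect r², F, t or p).
- Simple regression: OLS with intercept, two-sided slope p from t with
  n − 2 df. Multiple regression: intercept + log lifespan + log mass,
  per-coefficient t with n − 3 df, overall F on (2, n − 3).
- Chi-squared normality: observed counts in 5 bins against expected
  counts from a normal with the sample mean and SD; df = bins − 3 = 2,
  so the upper-tail p is exp(−χ²/2). Equal-probability bins are the
  default — at n = 16, equal-width bins can produce near-zero expected
  counts, which invalidates the statistic; equal-width is offered as an
  option because published values from small samples sometimes use it.
  With estimated parameters and equal-probability bins the attainable χ²
  values at fixed n are quantized, so reproductions of a published χ²
  should be read at the order-of-magnitude level unless the original
  binning is known.
- Q-Q points use plotting positions (i − 0.5)/n against standard-normal
  quantiles.
- No multiple-testing correction is applied across organs; the report
  says so explicitly and prints raw p-values.

## Trees and contrasts

Newick parsing, pruning and polytomy resolution are delegated to dendropy.
Pruning suppresses degree-2 nodes and sums their incident branch lengths;
polytomies are resolved into zero-length binary cascades with a seeded RNG
(the classic CAIC alternative — a single multi-way contrast per polytomy —
is not implemented; seeded resolution keeps the contrast count at n − 1
and is deterministic under a fixed seed).

Contrasts follow the standard recursion (post-order, first child minus
second child, ancestral values weighted by inverse branch lengths, parent
branches lengthened by v_i·v_j/(v_i+v_j)). Zero-length branches — e.g.
from polytomy resolution — are replaced by 1e−8 × the mean positive branch
length so contrast variances stay positive; the fraction is configurable.

Contrast–contrast regression is through the origin with r² defined against
the uncentered Σw² and df = n_contrasts − 1. Positivization (flipping each
pair so the predictor contrast is ≥ 0) is available for presentation and
provably does not change slope, r² or p. The through-origin contrast slope
equals the GLS slope under the Brownian covariance matrix; the test suite
checks this to 1e−8 relative on random trees against an oracle built
directly from shared path lengths.

**Branch lengths.** When divergence times are not supplied the pipeline
sets equal branch lengths (default 1.0, value immaterial — all contrasts
rescale identically). Equal lengths are applied *after* pruning to the
analyzed taxa, so the assumption refers to the analyzed species set rather
than to the full tree.

**Tree coverage.** Species present in the trait table but absent from the
tree are dropped from the contrast analysis only (with a logged reason)
and retained in the raw regressions; a strict mode errors instead. Labels
are matched exactly after trimming and space/underscore unification — no
fuzzy matching, since a silent misjoin is worse than a hard error.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not any particular data set:

- **Trait evolution.** Bivariate Brownian motion on the tree: each branch
  adds a normal increment with covariance (rate matrix × branch length).
  Default rates are chosen to match the observed scales of the real study
  system under unit branch lengths: 0.06 log₁₀-units²/branch for protein
  level (≈ 10-fold range across species), 0.02 for lifespan (3–31 years),
  0.25 for body mass (20 g – 55 kg); root states 0.5, 1.0 and 2.7 log₁₀
  units. Body mass evolves independently of the level–lifespan pair; any
  mass–lifespan association in simulated data arises from shared history
  alone.
- **Measurement layer.** Replicate lanes are packed first-fit in species
  order onto gels of fixed capacity (default 10 lanes), with one
  reference-species lane prepended to every gel. Lane intensity =
  true level × gel effect × lane noise × control level, with the control
  level reported as the actin band. Noise is multiplicative lognormal
  (intensities are positive and analyzed on the log scale), mean-one, with
  defaults lane CV 0.2, gel log-scale SD 0.1, actin CV 0.1 — small enough
  that the cross-gel adjustment is usually minor, as observed in practice.
  The layout is a fixture property, not a claim about real gels.

What the generator does **not** emulate: antibody affinity differences
between species (handled in real studies by epitope conservation checks;
the non-reactive species is an exclusion flag here, not a model),
saturation/censoring of bright bands, spatially correlated gel artifacts,
and non-Brownian trait evolution (no Ornstein–Uhlenbeck or early-burst
models). Passing tests therefore demonstrate correctness of the
computation under the model's assumptions, not robustness to violations
of them.

## Fixture and analysis subset

The packaged table carries the 16 species' maximum lifespans, adult body
masses and per-organ replicate counts. The packaged topology is assembled
from the consensus structure of published rodent phylogenies (a
squirrel-related clade, a mouse-related clade including the beaver, and
the hystricomorph clade) and is documented as an approximation for testing
and simulation. One species is flagged non-reactive with the target
antibody and excluded from analysis by default. Simulation testbeds use a
14-taxon subtree that additionally drops the one species with incomplete
organ coverage; the pipeline always reports the species list actually
used, since organ-level coverage varies.

## Problem sizes and numerical choices

Calibration checks use 1000 Brownian-motion replicates on the 14-taxon
subtree (≈ 13 000 contrasts); power checks use 500 end-to-end replicates
per condition, which bounds the Monte-Carlo SE of a rejection rate near
5% at about 1 percentage point. The GLS oracle comparison uses 100 random
trees of 4–10 leaves with uniform branch lengths on [0.1, 2]. Degenerate
inputs fail loudly: constant predictors, rank-deficient designs,
non-positive values entering logs, gels without reference lanes, and
missing leaf traits all raise errors naming the offending record.

## Known limitations

- No PGLS with estimated λ/κ/δ, no branch-length estimation, and no
  measurement-error-in-x regression; contrasts assume the supplied (or
  equal) branch lengths are correct.
- The chi-squared normality test at n = 16 is approximate; its type-I
  error is verified by simulation to lie in a 3–8% band at the 5% level
  rather than exactly at the nominal level.
- Reproduction of published statistics that depend on unpublished
  species-level means or on an unpublished tree is out of reach by
  construction; the package validates the procedure on data it can
  generate.
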