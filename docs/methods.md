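# Methods

## Census data model

The unit of observation is the leaf. A `LeafRecord` carries a specimen
id, quarry, stratigraphic level, morphospecies (or the sentinel
`UNIDENTIFIED`), a Raunkiaer size class (or `UNKNOWN`), a set of damage
types (DTs) and a `tally_count`. Field protocols often tally undamaged
leaves of recognizable morphospecies on the outcrop and discard them,
keeping only vouchers; such batches enter the table as first-class rows
with `tally_count > 1` and, by construction, an empty DT set. They
count toward floral abundance and toward damage-frequency denominators,
and they expand into individual undamaged leaves inside the rarefaction
universe, because the resampling unit is the leaf.

Unidentifiable leaves are retained in the table but excluded from all
species-level metrics, and all herbivory metrics are computed on
identifiable leaves only. Two DT encodings are read (wide 0/1 columns
named `DT<number>`, or a single `;`-separated list column) because
deposited census files vary in dialect. Quarries map to levels through
an explicit `unit_map`; level pooling is the disjoint union of the
level's quarries, so totals are conserved by construction. Unit and
variable labels are sorted lexicographically wherever an order matters,
making every output deterministic.

## Diversity and evenness

Shannon H uses the natural logarithm throughout, and Pielou's
J = H / ln S. This convention reproduces published two-decimal J values
from their printed (H, S) pairs (e.g., H = 1.26 over 12 species gives
J = 0.51), which is the check the acceptance suite runs. J is treated
as undefined below two species and rank-abundance ties are broken
lexicographically by taxon id.

## Rarefaction

Rarefaction is individual-based Monte Carlo: for each subsample size m,
draw m items without replacement, count distinct taxa, repeat
`n_resamples` times (default 1000), and report the mean with the
2.5/97.5 percentile band. Percentile rather than normal-approximation
intervals are used so no distributional assumption enters; with
strongly discrete richness distributions the sample mean can fall just
outside a percentile, so the band is widened to bracket the mean when
needed, keeping the documented invariant lower ≤ mean ≤ upper. One
permutation per resample serves all sizes at once (prefix trick), which
is exact because a uniform permutation's prefixes are uniform
subsets.

For species, the items are specimens; for DTs, the items are leaves,
undamaged ones included, and a leaf with k DTs contributes to k
richness columns. The Monte-Carlo mean converges to the hypergeometric
expectation Σᵢ [1 − C(N−nᵢ, m)/C(N, m)]; the test suite implements this
closed form (and the exact variance, including the union-based
covariance term needed when DT memberships overlap) as an independent
oracle and requires 3-standard-error agreement.

Species rarefaction sorts the abundance vector before expansion, so the
seeded draw depends only on the multiset of counts — this makes the
curve exactly invariant under permutation of its input, not merely in
distribution.

Per-host DT curves include only hosts with at least 20 identifiable
leaves in the unit (tally-expanded), the conventional threshold below
which damage-diversity comparisons are not considered meaningful.

## Herbivory metrics

Damage frequency is the share of identifiable leaves bearing at least
one DT of the category (any / specialized / generalized); a leaf counts
once per category regardless of how many qualifying DTs it bears, so
the category frequencies satisfy max(spec, gen) ≤ total ≤ spec + gen.
Specialization classes (mining and galling versus hole feeding,
skeletonization, surface and margin feeding, etc.) are supplied through
the DT registry rather than hard-coded, since class assignments follow
the damage guide in use. The specialized:generalized ratio is 0 when no
specialized damage occurs and flagged undefined (None) when generalized
damage is absent but specialized damage occurs, rather than raising.

## Paleoclimate proxies

Leaf-margin analysis: MAT = 30.6 P + 1.14 °C with binomial standard
deviation σ = 30.6 √(P(1−P)/r). P and r count morphospecies present in
the unit whose margin state is scored; species present only as
unidentifiable leaves, or with unknown margins, never enter.

Leaf-area analysis: MAP = exp(0.548 Σ aᵢpᵢ + 0.768) cm/yr, where pᵢ are
leaf proportions per Raunkiaer size class (UNKNOWN-class leaves removed
before normalization, tally-weighted) and aᵢ is the natural log of the
class's representative area in mm². The calibration's standard error
(0.359) is a log-scale quantity; exponentiating ±SE yields the
asymmetric linear-scale bounds +MAP(e^0.359 − 1) and −MAP(1 − e^−0.359).
This convention is adopted because it regenerates published asymmetric
bounds from their point estimates (145 → +62.6/−43.7; 142 → +61.3/−42.8
cm/yr); a linear-scale SE cannot produce asymmetry. The per-class aᵢ
are not universal constants: the default `SizeClassScheme` uses
geometric midpoints of the classic class boundaries (25, 225, 2025,
4500, 18225, 164025 mm², with the open-ended megaphyll class set to
twice its lower bound), and any calibration can be substituted via a
two-column CSV.

## Ordination

Unit × species and unit × DT count matrices feed Euclidean distances on
raw counts — no transform or standardization by default, since census
comparisons of this kind are conventionally run on counts; a transform
can be applied to the matrix before calling if desired. NMDS minimizes
Kruskal stress-1, √(Σ(d̂ᵢⱼ − f(dᵢⱼ))² / Σ d̂ᵢⱼ²), with f fit by isotonic
regression (ties averaged) via nonmetric SMACOF. Restart 0 starts from
the classical Torgerson metric-MDS configuration — which is already
exact whenever the distances are Euclidean-embeddable in k dimensions —
and subsequent restarts (default 20) from random Gaussian
configurations; the lowest-stress solution wins. Defaults:
max_iter = 300, tol = 1e−7. Because NMDS axes are arbitrary up to
rotation and reflection, the returned scores are centered, rotated to
principal axes, and sign-fixed by the largest loading, so repeated runs
are directly comparable. Variable scores place each species/DT at the
abundance-weighted mean of the site scores where it occurs; variables
absent everywhere get NaN coordinates as an explicit flag.

With five units in two dimensions the monotone transform leaves enough
freedom that stress < 0.01 is expected and observed (~3 × 10⁻⁴ on
synthetic censuses); non-convergence is flagged, never raised.

## Synthetic censuses

The generator emulates the statistical structure the analyses assume:
species drawn i.i.d. per leaf from a geometric (decay k, default 0.8
over a 40-species pool) or uniform rank-abundance model; margin state
fixed per species at pool creation with untoothed probability 0.65
(margin analysis scores species, not leaves); size classes i.i.d. from
a configurable spectrum centered on microphyll–notophyll; damage on
each leaf with probability 0.2, then 1–3 DTs drawn by weight without
replacement from a 34-DT pool (20 generalized, 14 specialized). The
defaults mirror a mid-Paleogene floodplain census in scale: five
units of ~300 leaves, ~20 species observed per unit, ~20 % damage
frequency, MAT ≈ 21 °C, MAP ≈ 125 cm/yr.

What it deliberately does not model: taphonomic and transport bias,
spatial autocorrelation within quarries, host-specific DT affinity
(available optionally via per-DT weights but off by default), and
level-to-level compositional turnover beyond sampling noise. Passing
tests therefore demonstrate correctness of the estimators on data
satisfying their assumptions, not robustness to preservational bias in
real assemblages.

`recovery_report` closes the loop: empirical damage frequency,
untoothed share and size-class frequencies are compared to their
configured values with exact Clopper–Pearson 95 % intervals (per-class
marginal intervals for the size spectrum).

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` from a single
  integer seed; identical configs produce byte-identical output files.
- Rounding is presentation-only: summary tables carry full-precision
  columns plus `_2dp`/`_1dp` display columns.
- Output files begin with `# key: value` provenance headers (package
  version, config hash, seed) and are never overwritten without an
  explicit flag.
- Problem sizes in the test and acceptance runs (1 500–2 000-leaf
  censuses, 1 000 resamples, 50–60 oracle comparisons) were chosen to
  exercise every code path at census-realistic scale while keeping a
  full run in seconds.
- Degenerate inputs raise informative errors rather than returning
  NaN: empty units, all-zero abundance vectors, subsample sizes beyond
  the sample, k ≥ n_units in NMDS, non-positive MAP.

## Known limitations

- Asymptotic richness estimators (Chao, ACE) are out of scope; curves
  interpolate only.
- Euclidean distance on raw counts makes ordinations sample-size
  sensitive; users comparing units of very different n may wish to
  transform the matrix first.
- The σ printed for a leaf-margin MAT depends on which species count r
  is used; when richness from pooled museum plus field collections
  differs from the margin-scored species count, published σ values may
  not be exactly recoverable.
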