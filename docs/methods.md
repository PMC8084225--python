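# Methods

## The equal-area annulus (EAA) statistic

Around every *focal* tree we lay `n_annuli` concentric rings whose radii

    r_k = sqrt(k * A_tot / (n_annuli * pi)),    k = 0 .. n_annuli

give each ring the identical area `A_tot / n_annuli` (default `A_tot` =
500 m², 10 rings, outer radius ≈ 12.62 m).  Equal areas mean equal expected
neighbor counts under homogeneity, so every physical-distance band carries
the same statistical power.  Rings are half-open `[r_{k-1}, r_k)`; a
co-located stem of a different tree falls in ring 1; a tree is never its own
neighbor.  Near the plot boundary the inside fraction of each ring is
computed exactly from circle–rectangle intersection geometry and annular
counts and basal areas are inverse-area weighted (`w = 1/fraction_inside`);
an alternative `drop` mode discards focal trees whose outermost ring falls
mostly outside.

Neighbors ("annular" trees) are cross-classified by ring and by the
phylogenetic distance between the focal and annular species, measured in Ma
back to their last common ancestor on a time-calibrated ultrametric tree.
All subdivisions of the data are *equal-count quantiles*: focal diameters in
four within-species quartiles, annular summed basal areas in five quintiles,
species-pair divergence times in 5–20 quantiles.  Because many species pairs
share exactly the same divergence time (every internal node spawns a whole
class of equidistant pairs), the ordering of tied pairs is reshuffled in
each of ten replicates, so tie classes straddling a quantile boundary are
dealt to both neighboring quantiles across replicates.  Conspecific pairs
(0 Ma) are pinned to the first quantile as the anchor class.

## The six tests and their null models

Each test compares an observed focal–annular statistic with a Monte Carlo
null in which a single focal attribute is permuted *within species within a
census interval*, leaving positions, species identities, and every annular
property untouched:

| test | statistic (per annulus × phylo quantile × group)                | shuffled attribute | NDD sign |
|------|------------------------------------------------------------------|--------------------|----------|
| 1    | mean edge-weighted summed basal area of annular survivors, by focal size quartile | focal sizes | − |
| 2    | pooled fraction of annular trees that recruit, by focal size quartile | focal sizes | − |
| 3    | pooled fraction of annular trees that die (all/small/large), by focal size quartile | focal sizes | + |
| 4    | mean normalized growth of the smallest focal size quintile, annular-biomass quintile minus the no-neighbor comparison group | normalized growth | − |
| 5    | pooled fraction of annular recruits around focal recruits          | demographic fates  | + |
| 6    | pooled fraction of annular deaths around focal deaths (small/large) | demographic fates  | + |

Recruitment is proxied by trees first reaching the 1 cm dbh census
threshold in an interval; the recruit-fraction denominator is all annular
trees present at the interval end.  Growth rates are normalized to SD units
within (species × census interval × start-diameter decile) strata; deciles
with fewer than 10 trees collapse into neighbors, and degenerate strata
(singletons, zero spread) normalize to 0, making the statistic scale-free
per species.  Annular trees that die are split at the per-species median
diameter into "small" and "large" groups (odd counts place the median tree
in "small").

Because the within-species shuffle conserves every pooled total, any
positive deviation in one size quartile must be balanced by negative
deviations in others for tests 1–3; the growth test has no such constraint.
Spatial clustering — including storage-effect cohort structure — is
identical in the real and shuffled data and therefore cannot inflate the
tests by itself.

### z-scores, replicates, and the pooled null

Per replicate the observed statistic is compared with `iterations`
(default 100) within-species shuffles: `z = (obs − null mean)/null SD`.
Cells with zero null SD are flagged undefined and excluded from the
multiple-testing family.  The *headline* z is computed on
replicate-averaged neighborhood tables — a pair tied across a quantile
boundary contributes fractionally to both quantiles — and compared against
all `replicates × iterations` shuffles pushed through the identical
pipeline.  This construction is an exact permutation test: under
within-species exchangeability the observed statistic is one more draw from
the same distribution as the null draws.  (Averaging per-replicate observed
statistics against single-binning nulls, the obvious alternative, is
mis-calibrated: tie shuffling moves whole pair classes between quantiles,
so the averaged observation has systematically less variance than any
single-binning draw; we measured z SDs near 0.7 under the null.)

Tests 5 and 6 need one further refinement.  Their statistics are
*quadratic* in the demographic labels — a recruit appears both as a focal
tree and inside its neighbors' annuli — so a null that permutes only the
focal-side labels while freezing the annular fate field captures roughly
half the variance (we measured z SD ≈ √2 on an exactly exchangeable plot).
The fate shuffle is therefore applied jointly: one within-species
permutation per draw relabels fates everywhere, and both the focal grouping
and the annular fractions are recomputed from it (evaluated at pair level
for speed).  Under label exchangeability this is again exactly calibrated.

Two-sided normal p-values from the pooled z are Benjamini–Hochberg adjusted
at `alpha` (default 0.05) within a family of all defined cells of one
(test × census interval).

## Smoothing

Curves of z against phylogenetic distance, and surfaces over (physical
distance, phylogenetic distance), are penalized regression splines:
cubic B-splines on equally spaced knots extended beyond the data range,
with a second-order difference penalty (so constants and straight lines are
unpenalized), smoothing parameter chosen by generalized cross-validation
(ties broken toward the smoother fit), and pointwise 95% bands from the
posterior coefficient covariance `sigma² (X'X + λP)⁻¹`.  Surfaces use a
tensor-product basis with one GCV-chosen penalty per axis; the physical
coordinate of an annulus is its area-weighted mean radius.  Grid points
whose fitted value lies inside the two-sided null band [−1.96, 1.96] form
the "gray" (non-significant) region.  The automated basis-size rule
(`choose_k`) accepts the smallest k whose effective degrees of freedom stay
below 0.9·(k−1) and whose x-ordered residuals show no lag-1 autocorrelation
at p > 0.05 — a scripted stand-in for an interactive basis-dimension check.
Extrema of a fitted curve are reported when the 95% band at the extremum
excludes the fitted value at its flanking turning points, ranked by
prominence.

## The synthetic plot generator

The generator emulates the structure of a stem-mapped forest plot:

* **Window and abundances.** A rectangular plot (default 100 m × 100 m,
  ~2000 stems ≈ 0.2 stems/m², inside the 0.035–0.829 range spanned by real
  plots).  Species abundances follow a log-series draw ranked by species,
  or an explicit per-species vector for designed communities.
* **Spatial pattern.** Per species, a Thomas cluster process (uniform
  parents, Gaussian offspring displacement, σ = 5 m); a CSR mode places
  stems uniformly.
* **Phylogeny.** A Yule tree rescaled to a 300 Ma root (angiosperm scale),
  or an explicit Newick string for designed communities; distances are MRCA
  depths.
* **Demography.** Per ~5-year interval: baseline mortality 0.10, diameter
  growth N(1.0, 0.5²) cm truncated at zero shrinkage, and recruitment as
  spatially explicit propagule arrival — 0.3 candidates per adult placed
  N(0, 5² m) around a random conspecific adult (or uniformly in the
  `uniform` mode), establishing with probability 0.8 and entering the
  census at just over 1 cm dbh.
* **Planted interactions.** Each effect multiplies log-scale rates by
  `strength × I`, where `I = Σ_j (BA_j/BA_ref) exp(−d_ij/ρ) W[sp_i, sp_j]`
  sums over living neighbors, `BA_ref` is the basal area of a 10 cm stem,
  and `W` is either the smooth kernel `exp(−Ma/λ)` or an explicit pair
  matrix (allelopathy, interaction valleys).  NDD raises mortality and
  suppresses recruitment and growth near large related neighbors; PDD is
  the mirror image.  Zeroed pairs (`plant_pair_null`) produce exact
  non-interaction "valleys".  Modulated probabilities are clamped to
  [1e−6, 1−1e−6] with a logged count.  Default `burn_in` = 2 intervals are
  simulated before the first recorded census so planted effects shape the
  standing size/spatial structure, not just the dynamic rates.

What the generator does **not** emulate: multi-stemmed architecture,
topographic or soil heterogeneity, disturbance (storms, fire), seed-bank
dynamics, and interannual climate variation.  Passing tests show the
statistical machinery recovers what was planted under these idealized
conditions; they do not certify behavior under real-data complications such
as habitat association confounding.

## Reference communities and problem sizes

The bundled scenarios fix the study conditions for the demonstration suite;
plot sizes (0.5–5 hectares, 2–15 thousand stems) were chosen so a complete
analysis runs in seconds to about a minute, one to two orders of magnitude
below real plots:

* **Neutral** (calibration): CSR positions, uniform recruitment, no
  effects — the regime where demographic labels are exchangeable against
  position, so all six nulls must reject at the nominal 5%.  A clustered
  plot with parent-placed recruits is deliberately *not* used here: spatially
  explicit recruitment creates genuine recruit–recruit clustering that the
  fate tests correctly detect.
* **Conspecific NDD**, one demographic channel at a time (mortality 0.4 at
  ρ = 3 m; recruitment 0.15 at ρ = 5 m; growth 0.1 at ρ = 5 m, identity
  phylogenetic kernel).  Single-channel plantings are used because
  channels interfere when combined — e.g. mortality thins the
  recruit-fraction denominator near large conspecifics and cancels the
  recruitment signal — mirroring the method's one-variable-at-a-time design.
* **Allelopathy**: a donor species 300 Ma from a 13-species angiosperm
  clade suppresses recruitment (0.45) and growth (0.30) of all angiosperms
  except the most abundant, immune, species.  Used for the physical-decay
  and surface-preservation checks and the species-removal protocol.
* **Valley**: a growth-suppressing NDD kernel (λ = 200 Ma) over a designed
  54-species tree in which two abundant implicated pairs (112 Ma) and most
  of a 64-pair clade class (111 Ma) have their interaction zeroed, with
  abundant anchor pairs at 95 and 125 Ma giving the shoulder quantiles
  statistical mass.  The growth channel carries this demonstration because
  its continuous response resolves per-quantile contrasts that the
  fraction-based tests cannot at these plot sizes.

## Intervention protocols

`manipulate_distances` rewrites chosen pair divergence times (both matrix
mirrors, ultrametricity deliberately not enforced) and the analysis is
re-run: features of the z-curves that track the pairs must move with them.
`subset_run` removes species independently from the focal and/or annular
sides (a species removed as annular still acts as focal and vice versa);
all quantile schemes are recomputed on the subset by default.

## Numerical choices and edge cases

* Coordinates live in the half-open rectangle [0, W) × [0, H); out-of-plot
  census records are rejected with a logged count.
* Species with fewer members than quantiles are ranked with ties sharing
  the lower bin; fully tied values are dealt uniformly by the replicate
  seed.
* All randomness flows from explicit seeds; identical seeds reproduce
  results bit for bit.  The tie-shuffle stream is separable
  (`tie_seed`) so tie-assignment sensitivity can be probed in isolation.
* Undefined cells (empty groups, zero denominators, constant statistics)
  are flagged, reported, and excluded from BH families — never silently
  dropped.

## Known limitations

* Desk-scale plots resolve planted effects of moderate-to-strong size;
  per-quantile contrasts of weak effects in fraction-based statistics
  (recruit/death fractions) are dominated by realization noise below a few
  tens of thousands of stems.
* The edge-correction literature the method descends from is not fully
  specified in public sources; inverse-area weighting is this package's
  declared choice, with the drop mode as a sensitivity alternative.
* The genus-level distance sampler reproduces only the uniform-depth rule;
  full megaphylogeny grafting is out of scope.
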