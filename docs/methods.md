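# Methods

## Phylogenetic distances

All phylogenetic computation starts from a rooted tree with branch
lengths.  The phylogenetic variance–covariance matrix `C` holds, for taxa
i and j, the shared root-to-tip path length (the depth of their most
recent common ancestor); its diagonal holds tip depths.  Patristic
distances follow as `d_ij = C_ii + C_jj - 2 C_ij`, which on any additive
tree equals the tip-to-tip path sum (tests verify this against an
independent path-length oracle).  The analysis is scale-covariant: branch
lengths may be in any unit, and every MPD-type statistic simply inherits
that unit.

Polytomies are resolved into dichotomies by repeatedly joining two
randomly chosen children of a multifurcating node under a new zero-length
internal node.  Zero-length edges are legal throughout; the resolution
changes no patristic distance, so all downstream statistics are invariant
to the resolution seed.  Ultrametricity is checked (relative tip-depth
spread below 1e-6) and reported but not enforced, because the math
requires only additivity.

Taxa observed in the field but absent from the tree can be supplied
through a sister-taxon substitution table (`observed_name,tree_name`): the
named tip is relabeled to the observed name, standing in at its sister's
position.  Observed taxa with neither a tip nor a substitution are
excluded from phylogenetic computations (with a log entry) but keep their
biomass in community totals and dissimilarities — unidentified species are
still weeds.

## Interspecific MPD and the relativized statistic

Abundance-weighted interspecific MPD is
`sum_{i != j} p_i p_j d_ij / sum_{i != j} p_i p_j` with `p_i` the relative
biomass of taxon i.  Only conspecific pairs (i = j) are excluded; two
distinct taxa separated by a zero-length resolution still count as an
interspecific pair at distance zero.  Fewer than two positive-abundance
taxa on the tree leaves the plot's value undefined; undefined values
propagate as flagged missing, never as zero.

The relativized statistic asks whether a cover crop is more or less
related to its weed community than expected from the resident flora.
`delta = MPD(cover + weeds) - MPD(weeds)` is computed twice — for the weed
community of a cover plot and for the weed community of its paired control
plot — and the difference of the two deltas is reported.  Conventions the
data do not dictate, chosen here and exposed as switches:

- **Cover abundance** (`cover_weight`): both delta terms use the cover
  plot's measured cover biomass (default `measured`), keeping the terms
  comparable so their difference isolates the weed-community shift.  The
  `unit` alternative assigns each cover taxon the mean positive weed
  biomass of the community it joins, an equal-footing variant.
- **Pairing** (`pairing`): each cover plot pairs with the control plot of
  its own site-year x block (default `block`), respecting the randomized
  complete block design; `site-pooled` pairs against the biomass-summed
  control community of the whole site-year.
- Mixtures contribute each component taxon with its own biomass.

Winter-type and summer-type experiments are analyzed separately; no
operation pools them.

## Community-structure tests

Bray–Curtis dissimilarities are computed on ln(1+biomass)-transformed
plot x taxon matrices.  A pair of all-zero plots is defined as 0
(identical emptiness, with a warning) and an empty vs non-empty pair as 1,
so the matrix is always total.  PERMANOVA partitions the Gower-centered
inner-product matrix `G = -1/2 J D^2 J` by sequential sums of squares in
the stated term order (site, treatment, site:treatment), with
`pseudo-F = (SS_term/df_term) / (SS_resid/df_resid)` and the add-one
permutation rule `p = (1 + #{F* >= F}) / (1 + n_perm)`; ties count as
exceedances (conservative).  Permutations relabel plots freely by default;
a `strata` option restricts them to within the levels of one design
column.  On univariate Euclidean instances the pseudo-F reduces exactly to
the classical one-way ANOVA F, which the tests exploit as an oracle.

Beta dispersion embeds plots by principal coordinates of `D`.  Axes with
negative eigenvalues (possible for Bray–Curtis) are kept as imaginary
axes whose squared contributions are subtracted from squared distances to
the group centroid, clamped at zero — the standard correction for
non-Euclidean dissimilarities.  The F statistic of a one-way ANOVA on the
centroid distances is referenced to a permutation distribution of group
labels.

Suppression is summarized per site x treatment as
`100 * (1 - treatment mean / control mean)` of total weed biomass
(unknown species included), pooling site-years and blocks within a site;
negative suppression is reported, not clipped, and a zero control mean
flags the site undefined.  Mixed-effects machinery (Tweedie or Gaussian
GLMMs, estimated marginal means, Fisher's LSD) is deliberately out of
scope: the block-paired t-test on per-plot MPD (treatment minus control
within each block) and the one-sample t-test on relativized values are the
package's desk-scale stand-ins, and are what the calibration studies
validate.  Per-treatment p-values are reported raw, with an optional Holm
adjustment.

## The synthetic experiment generator

The generator emulates a replicated field experiment: 2 sites x 2 years x
4 blocks x 5 treatments (four cover crops, one a two-species mixture,
plus a tilled control) = 80 plots, with crossed site-year and
block-within-site-year random intercepts on the log scale.  Weed biomass
is zero-inflated continuous — a Bernoulli occurrence times a Gamma
positive part — the support a Tweedie model assumes.

Suppression of weed i under a cover at patristic distance `d_i` is the
multiplier `m(d) = exp(-beta0 - beta1 * exp(-d/phi))`: `beta0` is the
baseline (relatedness-independent) suppression, `beta1 > 0` adds extra
suppression of close relatives, `phi` is the kernel range in branch-length
units (trees are simulated at depth 1, so `phi = 0.3` reaches only close
relatives while `phi = 1.5` grades suppression across the whole tree).
The multiplier is split across the two margins: occurrence is thinned by
`m**theta` and positive biomass scaled by `m**(1-theta)` (default
`theta = 0.5`), so the expected total-biomass ratio of a treatment to the
control is exactly `mean_i m(d_i)` — giving a closed-form suppression
oracle (`1 - exp(-beta0)` for a flat kernel) — while suppression still
changes species composition, not just abundance.  Mixtures suppress via
the nearer component (`min` distance kernel; a `sum` mode is available).

Default scale parameters (occurrence 0.35, Gamma(0.8, 170) kg/ha, random
intercept SDs 0.3 and 0.2, lognormal cover stands around 4 t/ha) put
control plot totals near 2 t/ha and cover treatments near 80% suppression
— magnitudes typical of cover-crop termination-time samplings.  They are
convenience defaults for realistic-looking data, not a fit to any dataset.

Cover taxa are placed at random tip positions of a seeded Yule tree over
the weed pool.  The Yule sampler is written in-package: lineages split
after Exp(k * birth rate) waiting times and a final exponential stretch
follows the last split, so terminal branches are positive and the tree is
exactly ultrametric, rescaled to depth 1.  Everything is reproducible
bit-for-bit from (tree seed, data seed).

### Repeated-simulation study design

`recovery_study` runs simulate -> MPD -> relativize -> t-test per
replicate and reports the mean statistic and rejection rate per parameter
point.  The reduced design used for repeated studies (one cover treatment
vs control, 2 sites x 2 years x 4 blocks, 16 weed species, occurrence
0.5) was fixed after a pilot power analysis: it yields ~16 pairings per
replicate with defined MPD nearly everywhere, at a cost allowing
thousands of replicates.

- **Calibration** uses the full no-suppression null (`beta0 = beta1 = 0`),
  under which cover and control weed communities are exchangeable and the
  relativized statistic is exactly symmetric about zero.  With
  `beta1 = 0` but `beta0 > 0` the statistic is only approximately centered
  (the two arms differ in richness), which would conflate calibration of
  the test with that approximation.
- **Power** uses `beta0 = 0.5, beta1 = 3, phi = 0.3` — a strong but
  short-range relatedness effect.
- **Community filtering** (lower weed MPD under cover than control) needs
  a kernel that grades suppression across the whole tree; at short range
  too few taxa are affected to restructure the community.  The
  strong-filtering point is `beta0 = 0.3, beta1 = 10, phi = 1.5,
  theta = 0.3`, with occurrence 0.7 and Gamma shape 1.5 to stabilize
  per-plot MPD.  Whether filtering truly lowers weed MPD depends on where
  the cover sits on each realized tree; `true_mpd_shift` computes the
  noise-free shift implied by a truth object, so detection can be assessed
  against the generating truth.

## Numerical choices

- Patristic entries are clipped at zero when rounding residue from
  zero-length arithmetic leaves values above -1e-12.
- Projection matrices in PERMANOVA come from a rank-revealing QR;
  degrees of freedom are projector traces, so collinear dummy codings are
  harmless.
- Permutation p-values use the add-one rule and count ties (within 1e-12)
  as exceedances.
- PCoA axes are kept when |eigenvalue| exceeds 1e-10 times the spectral
  radius; corrected squared distances are clamped at zero.
- In the block-paired contrast, a zero-variance set of differences is
  reported as t = 0, p = 1 when the differences are all zero (the exact
  null) and as an infinite t, p = 0 otherwise, rather than erroring.

## What passing tests do and do not show

The generator reproduces the design's statistical *structure* — blocked
randomization, zero-inflated biomass, distance-decaying suppression — so
passing calibration and recovery tests show the statistics are correct and
well-calibrated under that structure.  Real weed communities add features
the generator omits: spatial correlation within plots, seed-bank dynamics
and year carryover, species-specific emergence phenology (suppression here
depends on the phylogeny only through the distance kernel), measurement
error in biomass sorting, and taxonomic misidentification.  Results on
real data inherit none of the generator's guarantees; the pipeline's
value there is that each computational step is verified.

## Known limitations

- No mixed-effects modeling; block pairing absorbs block effects exactly
  only because MPD statistics are scale-invariant within plots.
- The relativized statistic's per-replicate t-test treats pairings as
  independent; pooling several cover treatments against a shared control
  introduces mild positive dependence (the reduced design avoids this by
  using a single cover treatment).
- Bray–Curtis between two empty plots is a convention (0), not an
  estimate.
- The beta-dispersion permutation test permutes raw centroid distances,
  which is slightly liberal relative to permuting residuals under
  unbalanced designs.
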