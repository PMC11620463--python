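# Methods

This note documents the models and procedures `enclospace` implements, the
assumptions and defaults behind them, and the places where a genuinely open
design choice had to be made.

## Enclosure geometry and surface unfolding

An enclosure is a rectangular box (length × width × height, cm) whose
interior floor and four walls form the surface an animal can occupy.  For
planar analysis the surface is unfolded into a cross-shaped net: the floor
stays central and each wall rotates outward about its shared floor edge.
The defining invariant is that a wall point at height *z* maps to planar
distance *z* from its hinge edge; consequently every panel's planar area
equals its 3-D area and the unfolding is exactly invertible.  Any hinged
layout satisfies the invariant — the cross was chosen because it keeps all
four flaps disjoint for every box shape.

Ceiling positions have no image on the 2-D diagram.  They are retained in
element-use tallies but excluded from density estimation, consistent with
analyzing floor-plus-wall surface use for a terrestrial animal that spends
its time on the ground and walls.  The "true surface area" used to convert
range proportions to cm² is floor + walls by default; an
`include_ceiling` switch exists for enclosures where that assumption is
wrong.

**Map-grid import.** Location fixes arrive as coordinates on a square
observation-app grid (600×600).  A `MapLayout` declares which rectangular
grid regions depict which panels; each region is scaled linearly onto its
panel.  The default layout inscribes the unfolded cross into the grid at a
single uniform scale.  Grid points outside every declared region raise an
error and are reported, never silently dropped.

**Rubbersheeting.** For maps whose drawn panels do not coincide with the
physical diagram, a control-point transform is provided: a global affine
least-squares fit plus smooth piecewise-cubic (Clough–Tocher) interpolation
of the residual displacements inside the control hull.  The contract is
exactness at every control pair, smoothness between controls, and decay to
the global affine fit outside the hull.  At least three non-collinear
control pairs are required.

**Zones.** A zone partition is an ordered list of named polygons tiling the
unfolded surface (areas must sum to the surface area within 1e-6 relative;
interiors pairwise disjoint).  Points on shared boundaries are assigned to
the earliest zone in partition order — an arbitrary but deterministic
tie-break.  Real studies should supply their hand-drawn zone map (YAML or
GeoJSON); the bundled default — Voronoi cells of the furniture centroids on
the floor plus a single wall zone — is a documented approximation used by
the synthetic pipeline.

## Fixed-kernel home ranges and core areas

Density estimation uses the fixed-kernel convention from wildlife ecology:

- bandwidth *h*<sub>opt</sub> = (2/(3*n*))<sup>1/4</sup> σ, where *n* is
  the number of fixes and σ the *standard distance*
  (√[Σ(xᵢ−x̄)² + Σ(yᵢ−ȳ)²]/n — the n-denominator GIS convention);
- a quartic (biweight) kernel with finite support, the common GIS choice;
  a Gaussian kernel is available as an option;
- the enclosure border acts as a barrier by clip-and-renormalize: kernel
  mass falling outside the unfolded surface is removed and the interior
  rescaled to total mass 1.  Reflection at the border was considered and
  rejected as a stronger assumption; the clipped-mass fraction is recorded
  on every density object so the choice is auditable.
- isopleths are the smallest-area cell sets holding 95% (home range, HR)
  and 50% (core area, CA) of the mass: cells ranked by density descending,
  ties broken by cell index, accumulated to the target.  This construction
  forces CA ⊆ HR and monotone area in the level.

The grid defaults to cells of min(length, width)/200, automatically
refined to ≤ *h*/2 so the kernel is always resolved; coarser user-supplied
cells are rejected.  The grid is padded by the kernel support so that
clipped mass is fully accounted.  Reported range sizes rescale the gridded
proportion by the analytic floor+wall area, removing discretization error
from the headline numbers.

Degenerate inputs: fewer than two fixes cannot yield a standard distance;
identical fixes give σ = 0 and a warned zero bandwidth (the density is a
point mass and no KDE is attempted in the pipeline).

## Zone electivity

For zone *i* with observed use *r<sub>i</sub>* (share of fixes) and
expected use *p<sub>i</sub>* (share of surface area),
*W<sub>i</sub>* = (*r<sub>i</sub>*/*p<sub>i</sub>*)/Σ<sub>j</sub>(*r<sub>j</sub>*/*p<sub>j</sub>*)
and *E\** = (*W<sub>i</sub>* − 1/*n*)/(*W<sub>i</sub>* + 1/*n*).  *E\** is
0 at use proportional to availability, −1 at total avoidance, and bounded
above by (1 − 1/*n*)/(1 + 1/*n*) at exclusive use.  Zones with zero
observed use are retained (W = 0, E\* = −1); zones with zero availability
are illegal and must be removed explicitly.  *E\** is computed per subject
and averaged across subjects with equal weight.  Fixes are pooled across
light phases by default (phase-stratified tables can be produced by
filtering the location stream).  The pipeline computes electivity for the
Complex condition only — with a single furniture element the Standard
enclosure offers too few zones to be informative — but nothing prevents
calling `zone_use` on any partition.

## Activity budgets and falls

Scan states are a closed, mutually exclusive vocabulary (Inactive,
Locomotion, Climb, Active in Place, Preen, Web Construction, Dig/Burrow,
Leg Raise, Other).  Per observation session, each state's proportion is
computed over *visible* scans only; sessions with no visible scans are
excluded with a warning rather than imputed.  Aggregation is two-stage —
session proportions averaged within subject, then mean and SD across
subjects — so every animal contributes equally regardless of completed
sessions, and reported SDs are across subjects (the across-observation
alternative is easily obtained from the subject-level table).  Falls are
all-occurrence events and enter as a rate per observation in a separate
accumulator; they are never mixed with scan proportions.

Hours are classified dark (1700–0600), light (0700–1500), or excluded
(the 1600 hour, whose lighting was inconsistent in the study design this
package mirrors).  Paired condition differences use the t distribution
with *n*−1 degrees of freedom on within-subject differences.

## Effect models

Each response is modeled against housing condition and sex (treatment
coding, reference levels Standard/female) with a random intercept per
subject.  Families:

- **Gaussian** (weight, HR size, CA size): `statsmodels` MixedLM, REML.
- **Binomial** (behavior, wall use, feeding, novelty activity): the
  proportion of successes with the visible-scan count as binomial total,
  fitted by maximum likelihood with 25-node Gauss–Hermite quadrature over
  the subject intercept; optimization is delegated to scipy (L-BFGS-B with
  a Nelder–Mead polish), standard errors come from the inverse numerical
  Hessian.  No maintained Python package currently provides a frequentist
  binomial GLMM, which is why the likelihood is assembled here; the fitter
  is cross-checked in the test suite against R's glmmTMB (coefficients and
  SEs agree to well under 1%), and a `backend="glmmtmb"` option delegates
  the whole fit to R when an installation is available.

A second crossed random intercept for observation date is honored only by
the glmmTMB backend: quadrature over crossed effects is intractable, and
in the balanced designs this package targets the date term changes
subject-level contrasts very little.  The default backend therefore fits
subject intercepts only; the choice is recorded on the fitted object.

Estimated marginal means average the linear predictor over the other
factor's levels with **equal weights** (the proportional-weighting
alternative is a one-line change in the contrast vector but is not the
default), and are back-transformed from the link scale; CIs use link-scale
standard errors.  Contrasts are odds ratios (exp of the logit-scale EMM
difference) for binomial models and EMM ratios with a log-scale
delta-method CI for Gaussian models.  Collinearity is screened by VIF
(auxiliary regressions with intercept; flag above 2.1).  Models whose
Pearson/raw residual skewness exceeds |1| are flagged for descriptive
reporting instead of model-based summaries, mirroring the practice of
presenting skewed-residual responses descriptively; the threshold is
configurable and recorded.

## Novelty and preference tests

The novelty test scores each subject × prior-condition exposure (≈40
scans at 15-s intervals) as the proportion of scans active (any
non-Inactive state) and in wall contact; the activity proportions feed the
binomial effect model.  The preference test reduces chamber interval
records to: first choice (chamber of the first interval outside the
selection chamber; "none" if the subject never left), entry counts
(adjacent same-chamber intervals coalesce, so counting is invariant to how
the video was segmented — an "entry" requires visiting another chamber in
between), and dwell proportions over the two housing chambers with
selection-chamber time excluded.  A full-body crossing is assumed to
define chamber membership; partial crossings are not modeled.

## Synthetic data generator

The generator emulates the full study: 13 subjects (3 male), two 4-week
housing blocks in counterbalanced order, 48 sessions per condition with
hours balanced around the clock (including the to-be-excluded 1600 hour),
20 behavior scans and 6 location fixes per session, weekly feeds, start/end
weights, 40-scan novelty tests, and a 24-h preference trajectory.

- **Behavior**: Bernoulli scans with logit-scale activity
  η = logit(0.04) + β·Complex + δ·light + u, subject intercepts
  u ~ N(0, τ²), τ = 0.5 by default; active scans are distributed over the
  active states with fixed weights.  Defaults put inactivity near
  0.95–0.98, matching the magnitudes the analysis is designed for.
- **Locations**: with a per-condition wall affinity (defaults 0.10
  Standard, 0.02 Complex — the Standard enclosure elicits far more wall
  time) a fix is uniform on the wall flaps; otherwise it is drawn on the
  floor from a mixture of truncated bivariate normals centred on
  attraction elements (rejection-sampled into the floor, spread 4 cm)
  plus a uniform background.  Attraction-drawn fixes are "In Hide" with
  probability 0.35, putting night hide use near 0.26.  These are labeled
  defaults calibrated to realistic magnitudes, not ground truth.
- **Falls**: Poisson per session with condition × phase rates (defaults
  0.023/0.003 dark, 0.015/0.014 light per observation).
- **Novelty**: activity logit base logit(0.06) plus log(2.5) after the
  Complex block, subject intercept τ = 0.5.
- **Preference**: a continuous-time Markov walk over
  {Selection, Standard, Complex}; exits from the selection chamber at 0.25/h
  (split p : 1−p between sides, p = 0.5 by default), chamber exits at
  0.15/h.  Symmetric rates give expected dwell 0.5; with equal exit rates
  the expected dwell ratio equals the entry-probability ratio.

What the generator does **not** emulate: behavioral autocorrelation within
sessions, movement paths (fixes are i.i.d. given the subject's mixture),
molt/feeding physiology, observer error, or drift over the study.  Tests
passing on synthetic data therefore validate the estimators and their
contracts, not the biology of any particular dataset.

## Problem sizes used in the checks

The bundled verification suite uses closed-form worked examples for the
geometry and index formulas; a 100-replicate coverage study for the
binomial mixed model at the study's scale (12 subjects, 96 sessions each,
true odds ratio 2.5); a 10-subject × 300-fix Monte-Carlo null for the
electivity index; 100-replicate two-cluster recovery for the core-area
estimator; and 200 trajectories for the preference symmetry null.  The
end-to-end pipeline examples run the full default study size (13 subjects,
1,248 sessions, ~25,000 scans).

## Known limitations

- The exact kernel, barrier algorithm, and georeferencing control points
  used by GIS toolchains are implementation-defined, so range sizes from
  other software will differ in detail; the bandwidth rule, isopleth
  construction, and areas here are exactly as documented above.
- The default zone partition is a geometric stand-in for a hand-drawn zone
  map; supply real zone polygons for substantive analyses.
- The quadrature GLMM supports one random-intercept grouping; use the R
  backend for crossed subject × date intercepts.
- Preference-test inference is descriptive; no latency/survival analysis
  is provided.
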