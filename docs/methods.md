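# Methods

`mcpr` re-implements, end to end on synthetic data, a standard analysis of
modern-contraceptive utilization from a two-stage cluster household survey:
sample screening and variable construction, descriptive screening, a
district random-intercept logistic model with intraclass correlation and
average marginal effects, road-network travel-time accessibility to health
facilities, and Jenks natural-breaks district classification.

## The outcome model

For woman *i* in district (community/PSU) *j*,

    logit P(y_ij = 1 | x_ij, u_j) = β0 + Σk βk x_kij + u_j,
    u_j ~ N(0, σ_u²),

where *y* indicates use of a modern method (versus a traditional method)
among women using any method. Fixed covariates enter at two levels:
individual characteristics (age group, marital status, household-head sex,
parity, pregnancy-termination history, education, media exposure, child
wantedness, wealth, religion, employment) and district aggregates
dichotomised at the median of the district distribution (community age
composition, socioeconomic status, family-planning media access,
education, health-facility access, majority residence).

Four models are fitted in sequence: (1) empty — intercept and random
intercept only; (2) individual terms; (3) community terms; (4) both.
Models are compared by AIC (2k − 2ℓ, audited as an exact identity in the
tests) and nested models by the likelihood-ratio test. The latent-scale
intraclass correlation is ICC = σ_u² / (σ_u² + π²/3), the share of latent
outcome variance between districts under the logistic link.

### Estimation

The marginal likelihood integrates the random intercept out per cluster.
Each one-dimensional integral is evaluated by **adaptive Gauss–Hermite
quadrature** (default 7 nodes): the integrand's mode and curvature are
found per cluster by a vectorised Newton iteration, and the quadrature
grid is centred and scaled there. At 7 nodes the log-likelihood agrees
with a dense trapezoid integration over u ∈ [−10σ, 10σ] to better than
1e-6 on test fixtures, and with 15-node quadrature to the same order.
σ_u = 0 is handled exactly as the ordinary logistic likelihood.

Optimisation is BFGS on (β, log σ_u), started from the fixed-effects-only
logistic (IRLS) fit with a second documented start at a larger variance.
Gradients are finite-difference: with adaptive quadrature the node
positions depend on the parameters through the cluster modes, so the exact
analytic gradient buys little for its complexity; agreement with the
independent `lme4::glmer` (nAGQ = 7) fitter is ~1e-5 relative on test
fixtures, which bounds any gradient-induced error well below statistical
noise. Standard errors come from the inverse observed information
(central-difference Hessian); the CI for σ_u² is formed on the log-σ scale
and back-transformed. Implausibly large coefficients (|β| > 20) raise a
separation error rather than returning a silent non-answer.

**Average marginal effects** are discrete changes in the
population-averaged probability: for category *c* of a covariate, every
woman's covariate is set counterfactually to *c* and then to the reference
level, the random intercept is integrated out (20-node Gauss–Hermite) in
each case, and the AME is the sample mean of the difference. Standard
errors use the delta method with a numerical Jacobian. The model-level
"Wald chi-square" tests all non-intercept fixed effects jointly.

### Known statistical limitations

- LR tests of *district-level* fixed effects rely on the number of
  clusters, not the number of women; with few districts (≲60) the test is
  anticonservative. The calibration suite therefore verifies nominal size
  at 100 clusters; users with fewer clusters should interpret
  community-term p-values cautiously.
- σ̂_u² is the unpenalised MLE and carries the usual small downward
  finite-sample bias; at the default design (hundreds of clusters) the
  median estimate is within a few percent of truth.

## Synthetic data

The real women's-recode file is access-restricted, so the generator is a
first-class module that emulates its structure rather than its records:

- **Hierarchy.** Districts (default 112, the number of modelled
  communities) each contribute a configurable number of women (default
  165, ≈18.5k interviewed in total). District effects u_j are drawn from
  N(0, σ_u²), default σ_u² = 0.10.
- **Screening.** Any-method use (p ≈ 0.557) and current pregnancy
  (p ≈ 0.103) are drawn so that screening — drop non-users, then drop
  pregnant users — lands the analytic sample near 9.2k, matching the
  published flow accounting; the run log verifies
  `n_input − n_nonusers − n_pregnant = n_analytic` exactly.
- **Covariates** are drawn independently per woman from configurable
  category margins defaulting to the published univariate distribution.
  The media composite is drawn at the composite level (so its margins hold
  exactly) and the three raw frequency items are drawn consistently with
  it. The published combined secondary+ education share (35.7%) is split
  30.0/5.7 between secondary and higher, and the collapsed wealth margins
  are halved between their constituent quintiles; both are package
  choices, configurable.
- **Effects.** Default log-odds effects are sign-matched to the study's
  reported directions (marriage, education, wealth positive; female
  household head, termination history, Islam/other denomination, community
  facility access negative) at modest magnitudes detectable at the default
  n. Community effects enter the generator through the same
  aggregate-then-median-split dummies the analysis uses. Unless β0 is
  given explicitly it is calibrated by a first-moment correction so the
  marginal modern share targets the published 53.2%.
- **What it does not emulate:** DHS sampling weights and design strata,
  covariate correlation (available via an explicit configuration only),
  item nonresponse, and any real spatial pattern. Passing tests therefore
  demonstrate correctness of the *methods* under the model's own
  assumptions, not properties of the real survey.

The toy geography is a planar km-grid road network (five national road
classes drawn with fixed weights), health facilities jittered near roads
(with a configurable fraction deliberately placed beyond the snap
tolerance), circular lakes overlapping roads, and a rectangular district
tiling. A flat CRS suffices because travel time needs only lengths and
speeds.

## Variable construction

- Method codes classify as modern (sterilization, IUD, injectables,
  implants, pill, condoms, emergency contraception, other modern) or
  traditional (rhythm, withdrawal, lactational amenorrhea, other
  traditional) via a packaged YAML vocabulary; unknown codes raise an
  error naming the code.
- Media composite: each of three items (newspaper, radio, TV; codes 0/1/2)
  recodes to access 0/1; the sum S ∈ 0..3 splits at the median — 0 low,
  1 medium, 2–3 high.
- Education collapses secondary and higher; wealth collapses the five
  quintiles to poor/middle/rich.
- Community variables: district proportions dichotomised at the median of
  the district-level distribution, ties assigned high. The exact cut point
  for such high/low aggregates is not standardised in this literature; the
  median split with ties-high mirrors the media-composite rule above and
  is configurable. Residence is a
  district majority vote (ties → urban). The family-planning media
  indicator is a distinct configurable column rather than a reuse of the
  three-item composite, since the source leaves this open.

## Descriptives and screening

Crosstab percentages follow the published convention — outcome columns are
percent of the **grand total**, so the two outcome columns sum to each
category's overall share (a row-percent option exists). Pearson chi-square
is computed without continuity correction (Yates optional for 2×2).
Variables with bivariate p < 0.05 proceed to a VIF screen
(VIF_k = 1/(1−R²_k) on the dummy design; exact collinearity reported as a
flagged infinity) with threshold 10. Published percentages that are
internally inconsistent with their counts are recomputed from counts,
never force-matched.

## Accessibility analysis

Edges are weighted by driving minutes = length / class speed × 60 with
national speeds {primary 120, secondary 80, tertiary 60, residential 40,
tracks 20} km/h; a fixed assigned-minutes-per-class mode
(30/45/60/90/180) is available for fidelity experiments against workflows
that assign one time per road type. Lakes remove every edge intersecting
their interior (nodes kept, removals logged). Facilities snap to the
nearest point on the nearest edge within 15 km (the WHO's 5 km facility
radius, doubled for rural settings and extended for lake regions), the
edge being split at the projection — snapping to the nearest existing
node instead would distort times on coarse rural segments. Facilities
beyond tolerance are reported as unlocated and excluded. Roads are
undirected with symmetric speeds, so "towards the facility" equals the
multi-source shortest-path direction. Per-node minimum minutes to any
located facility are banded into six non-overlapping half-open intervals
(0–30, 30–45, 45–60, 60–90, 90–180, 180–240]; beyond 240 minutes or
disconnected is unreachable. Demand points default to district centroids
(real survey coordinates are displaced; per-woman points are supported);
each district reports band shares, weighted median minutes, and a
four-hour flag.

## District classification

Jenks natural breaks by exact dynamic programming over sorted values,
minimising total within-class squared deviation; ties prefer smaller upper
bounds. Five classes by default, with the lowest class reserved for
no-data **and** zero-valued districts (the conventional reading of a map
whose smallest class "at 0" includes districts without data); remaining
positive values fill the upper classes, so a single valued district lands
in the top class and the top bound equals the data maximum. The mapped
quantity is each district's share of all modern users nationally — the
only reading consistent with published district values topping out near
7.7% while within-district prevalence is ~50% — with within-district
prevalence also reported. Goodness-of-variance fit (1 − WSS/TSS) is
reported for transparency.

## Reproducibility and problem sizes

One master seed drives every stage through deterministically derived child
seeds; rerunning any stage with the same seed is byte-identical, including
GeoJSON exports. The simulation-based validation suite uses 100 replicates
of the 200-district × 50-women design (σ_u² = 0.10) for parameter
recovery and 500 replicates of a 100-district × 10-women design for LR
size calibration — sizes chosen so the whole suite completes in a few
minutes on one CPU while keeping Monte-Carlo error small relative to the
tolerances checked. The acceptance script runs the full default design
(112 × 165) end to end.
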