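# Methods

## Model

A historical cohort mortality study with a polytomous exposure tabulates,
per stratum, the cause-of-interest deaths (cases) and the non-cases, the
latter split into subjects classified alive at study end and subjects who
died of other causes. Subjects lost to follow-up are by convention carried
as living non-cases, so lost decedents from the cause of interest deflate
the case cells. Writing the observed crude odds ratio as the product of
the adjusted odds ratio and a multiplicative error factor,

    OR_observed = ε · OR_adjusted,

the package estimates the distribution of ε (and of OR_adjusted) induced
by explicit probability distributions on the classification parameters,
via Monte Carlo simulation.

Each trial draws, in order:

| stage | quantity | law | support |
|---|---|---|---|
| 1 | AD, all-cause deaths among the lost | truncated negative binomial(p, r) | [0, n_lost] |
| 2 | ID, cause-specific deaths | BetaPERT(0, q·AD, AD), integer-truncated | [0, AD] |
| 3 | ID_never, allocated to the reference stratum | BetaPERT(0, f·ID, ID), integer-truncated | [0, ID] |
| 4 | ID_high, allocated to the highest stratum | BetaPERT(0, ½·ID_ever, min(ID_ever, cap)), integer-truncated | [0, min(ID_ever, cap)] |

with ID_ever = ID − ID_never and the residual ID_middle = ID_ever −
ID_high assigned to the middle stratum for bookkeeping only (it never
enters the two-stratum odds ratio). The supports are nested: each stage's
maximum is the previous stage's drawn value, so conservation
ID_never + ID_middle + ID_high = ID holds in every trial by construction.

The adjusted 2×2 table moves the drawn decedents from living non-case to
case within their stratum (row totals conserved):

    a = cases_high + ID_high      b = noncases_high − ID_high
    c = cases_ref  + ID_never     d = noncases_ref  − ID_never

and OR_adjusted = (a/b)/(c/d), ε = OR_observed / OR_adjusted.

### Assumptions

- Losses can only have been misclassified if they were tabulated as
  *living* non-cases; hence the stage-4 cap equals the living non-cases of
  the highest stratum (112 in the bundled cohort), and a defensive cap at
  the reference stratum's living non-cases is applied for foreign tables
  (it can never bind on the bundled cohort, where 414 > n_lost = 338).
- The cause-specific death proportion q is taken from external
  population mortality data and treated as constant over the study period.
- The residual-split allocation is specific to a three-level exposure;
  deeper allocation chains are out of scope.

## Distribution choices and parameters

**Truncated negative binomial** (stage 1). Convention: number of failures
before the r-th success, success probability p, so the support starts at
0 and can include it. Truncation to [0, n_lost] renormalizes the pmf over
the finite support (sampling is inverse-CDF on the enumerated,
renormalized pmf); clamping is deliberately avoided since it would pile
mass on the bounds. The bundled scenarios use the published pairs
(p=0.02, r=3), peaking near 104 (the observed death proportion of the
highest-exposure stratum, 30.9%, times the 338 lost), and
(p=0.027, r=2), peaking near 37 (the never-exposed proportion, 11.0%).
Note the (0.02, 3) mode is 98, a few counts below trunc(0.309·338) = 104:
a (probability, shape) law cannot be pinned to an arbitrary peak exactly.
`fit_negbin_from_mode` constructs a spec from (minimum, likeliest,
maximum) for new studies by grid search over (p, shape) with ties toward
the smaller shape, using the closed-form mode floor((r−1)(1−p)/p) clipped
to the support (valid because the pmf is unimodal).

**BetaPERT** (stages 2–4). Beta re-parameterized by (minimum, likeliest,
maximum) with shape weight λ: α = 1 + λ(mode−min)/(max−min),
β = 1 + λ(max−mode)/(max−min), rescaled to [min, max]. λ = 4 (the classic
PERT) throughout; at λ → 0 the law degenerates to the uniform, which the
tests exercise as a regression check. Continuous draws are truncated
toward zero to integers; the truncation's effect on geometric-mean
summaries is negligible, which the original analysis also observed.
Modes are passed in continuous form (e.g. q·AD = 21.216 when AD = 104 and
q = 0.204); only drawn values are truncated.

**Degenerate and zero draws.** When a stage's maximum equals its minimum
the draw is that point. A zero at any stage zeroes all downstream stages
of the trial (zero-propagation); such trials are kept, since discarding
them would bias the ε distribution toward larger misclassification.

**Open choice, stage 4.** When ID_ever exceeds the cap, the mode is taken
as min(½·ID_ever, cap) so that mode ≤ max always holds; the alternative
(mode ½·ID_ever with a clipped max) would violate the PERT's
parameterization.

## Simulation and summaries

Each scenario runs n_trials (default 50,000) under a single seeded
`numpy.random.Generator`. The engine is vectorized stage by stage: all AD
values are drawn first, then all stage-2 draws for trials with AD > 0, and
so on, with the stream consumed in fixed stage order — runs replay exactly
for a given seed. The scalar `draw_trial` provides the same chain one
trial at a time for audit and testing (its stream consumption order
differs from the vectorized engine's, so per-trial values match the
vectorized run only in distribution).

Ratio-scale outputs are summarized by the geometric mean
exp(mean(ln x)) — defined for every trial because the adjusted cells are
bounded away from zero on the bundled cohort (cases ≥ 14; the highest
stratum retains at least its 36 other-cause decedents) — and by empirical
certainty intervals: the (1−level)/2 and 1−(1−level)/2 quantiles of the
trial values with linear interpolation between order statistics (any
standard convention differs negligibly at 50,000 trials; the convention
is pinned for reproducibility). Certainty intervals are percentile
summaries of the simulation distribution, not confidence intervals.
Histograms (default 50 equal-width bins) are exported with their edges so
frequency-distribution figures can be rebuilt downstream. For foreign
tables whose adjusted cells could reach zero, affected trials are flagged
and summarization refuses to proceed until they are inspected; trials are
never silently dropped.

The crude measures use the Wald interval on the log-odds-ratio scale with
no continuity correction, which reproduces the bundled cohort's published
1.42–6.54 at the 95% level.

## Synthetic tables

`generate_synthetic_table` produces random valid cohort tables (positive
cells of occupational-cohort magnitude, alive + deceased = non-cases,
n_lost up to a quarter of the cohort) to property-test the pipeline on
non-fixture data. It emulates table *structure* only — counts are drawn
independently, with no exposure–mortality association and no relation
between n_lost and stratum sizes — so passing tests on synthetic tables
demonstrate structural invariants (conservation, caps, determinism), not
epidemiological realism.

## Numerical notes

- The negative binomial (0.02, 3) pmf ties at cells 97 and 98 to machine
  precision; tests accept either argmax.
- `fit_negbin_from_mode` breaks exact-score ties toward the smaller
  shape, then toward the candidate whose continuous untruncated mode is
  nearest the target.
- Integer truncation is toward zero (`numpy.trunc`), which equals floor on
  the non-negative supports used here.
- Counts are strict integers; floats (and bools) are rejected rather than
  rounded.

## Problem sizes

The default test suite runs the eight bundled scenarios at their full
50,000 trials (the vectorized engine completes all eight in about a
second) and the distribution-law oracle checks at 10⁵–5·10⁶ draws. The
acceptance script runs Scenarios 1 and 2 at 50,000 trials each.

## Known limitations

- The allocation chain is specific to three exposure strata (reference,
  middle, highest); arbitrary-depth allocation is not modelled.
- Only the loss-to-follow-up disease-misclassification error term is
  modelled; exposure misclassification, confounding and other error
  sources would multiply into the same decomposition but are out of scope.
- A time-varying cause-specific death proportion is not modelled; if the
  true proportion declined over the study period, analyses using a single
  recent proportion may understate the misclassification.
- Person-time measures (rate ratios, SMRs) are out of scope; the method
  requires a count-based estimator.
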