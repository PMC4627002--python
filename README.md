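# ltfbias

Probabilistic bias analysis (Monte Carlo uncertainty analysis) of **disease
misclassification caused by loss to follow-up** in historical cohort
mortality studies with multi-level exposure.

## The problem

Retrospective occupational mortality cohorts routinely lose a fraction of
their subjects to follow-up. When the analysis uses an odds ratio (or
incidence proportion ratio), the lost subjects are tabulated as alive at
study end — so any of them who in fact died of the outcome of interest are
counted as living non-cases, never as cases. The crude odds ratio is
therefore biased, in a direction that depends on how the lost decedents
were distributed across exposure strata.

`ltfbias` quantifies and adjusts for this error. The observed odds ratio
decomposes as

```
OR_adjusted = OR_observed / ε
```

where ε is the multiplicative error factor for disease misclassification
due to loss to follow-up (ε > 1: the crude estimate overstates the
adjusted association; ε < 1: it understates it). Because the true
classification parameters are unknown, each is given a probability
distribution and propagated through Monte Carlo simulation:

1. **AD**, the all-cause deaths among the `n_lost` subjects — a negative
   binomial (probability `p`, shape `r`), truncated (renormalized, not
   clamped) to `[0, n_lost]`;
2. **ID**, the deaths from the cause of interest —
   BetaPERT(0, q·AD, AD), with `q` an external cause-specific death
   proportion;
3. **ID_never**, the share allocated to the never-exposed (reference)
   stratum — BetaPERT(0, f·ID, ID), with `f = 3/4` when the never-exposed
   are assumed *more* likely to be misclassified as alive ("Differential
   A") and `f = 1/4` when *less* likely ("Differential B");
4. **ID_high**, the share of the remaining ever-exposed deaths allocated
   to the highest-exposure stratum — BetaPERT(0, ½·ID_ever,
   min(ID_ever, cap)), where the cap is the number of *living* non-cases
   in that stratum (decedents of other causes cannot have been
   misclassified as alive).

Continuous PERT draws are truncated toward zero to whole counts; a zero at
any stage forces all downstream values of that trial to zero
(zero-propagation), and such trials are retained. Each trial moves the
drawn decedents from "living non-case" to "case" within their stratum,
yielding an adjusted 2×2 table, an adjusted odds ratio and ε. A scenario's
50,000 trials are summarized by geometric means and empirical 95%
*certainty intervals* (percentiles of the simulation distribution).

The bundled fixture is a three-stratum trichlorophenol-worker cohort
(ischemic heart disease vs. cumulative TCDD exposure; 338 of ~1600 workers
lost to follow-up) together with the eight published bias scenarios that
cross two all-cause-death peaks (104 and 37 of the 338 lost), two
cause-specific proportions (0.204, 0.139) and the two differential
directions.

## Worked example

```python
import ltfbias as lb

table = lb.builtin_table()               # the bundled cohort counts
scenarios = {s.name: s for s in lb.builtin_scenarios()}

model = lb.LossToFollowUpBiasModel(table, scenarios["2"])
results = model.fit(seed=1)              # 50,000 Monte Carlo trials
print(results.summary())
```

```
Loss-to-Follow-Up Bias Analysis Results
=======================================================
Scenario:             2
Exposed stratum:      >=2085.8 ppt-mo
Reference stratum:    never-exposed
Trials:               50000   (seed 1)
-------------------------------------------------------
Observed crude OR:    3.05  (95% Wald CI 1.42-6.54)
GM adjusted OR:       3.33  (95% certainty interval 1.20-10.72)
GM error factor:      0.92  (95% certainty interval 0.28-2.53)
OR interval width:    9.51
=======================================================
```

The crude odds ratio of 3.05 compares ischemic-heart-disease mortality in
the highest-exposure stratum (odds 14/148 = 0.0946) with the never-exposed
stratum (14/451 = 0.0310). Under this scenario — the never-exposed *less*
likely than the highest-exposed to have lost decedents counted as alive —
the geometric mean adjusted odds ratio (3.33) moves away from the null and
the error factor is below one: the crude estimate understates the
association. The certainty interval (1.20–10.72) shows how much
uncertainty the unknown fate of the 338 lost subjects adds. Per-trial
records are available from `results.to_frame()`.

The same analysis runs from the shell:

```
ltfbias --table builtin:mcbride --scenarios all --seed 1 --output-dir out/
```

which writes a per-scenario summary table (`summary.tsv`), structured full
results with histograms (`results.json`) and, with `--audit`, per-trial
audit files.

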