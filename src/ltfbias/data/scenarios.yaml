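# Eight bias-analysis scenarios for the bundled trichlorophenol cohort.
#
# allcause: truncated negative binomial for the number of all-cause deaths
#   among the 338 lost to follow-up.  Scenarios 1-4 peak near 104
#   (= trunc(30.9% of 338), the observed death proportion of the highest
#   exposure stratum); 5-8 peak near 37 (= trunc(11.0% of 338), the
#   never-exposed stratum's proportion).
# cause_proportion: external proportion of all-cause deaths due to ischemic
#   heart disease (0.204 non-Maori males; 0.139 Maori females, 2008 New
#   Zealand mortality data).
# differential: A = never-exposed more likely misclassified as alive
#   (mode fraction 3/4); B = less likely (1/4).
# high_cap: living non-cases in the highest exposure stratum.
scenarios:
  - name: "1"
    allcause: {probability: 0.02, shape: 3, lower: 0, upper: 338}
    cause_proportion: 0.204
    differential: A
    high_fraction: 0.5
    high_cap: 112
    n_trials: 50000
    seed: 1001
  - name: "2"
    allcause: {probability: 0.02, shape: 3, lower: 0, upper: 338}
    cause_proportion: 0.204
    differential: B
    high_fraction: 0.5
    high_cap: 112
    n_trials: 50000
    seed: 1002
  - name: "3"
    allcause: {probability: 0.02, shape: 3, lower: 0, upper: 338}
    cause_proportion: 0.139
    differential: A
    high_fraction: 0.5
    high_cap: 112
    n_trials: 50000
    seed: 1003
  - name: "4"
    allcause: {probability: 0.02, shape: 3, lower: 0, upper: 338}
    cause_proportion: 0.139
    differential: B
    high_fraction: 0.5
    high_cap: 112
    n_trials: 50000
    seed: 1004
  - name: "5"
    allcause: {probability: 0.027, shape: 2, lower: 0, upper: 338}
    cause_proportion: 0.204
    differential: A
    high_fraction: 0.5
    high_cap: 112
    n_trials: 50000
    seed: 1005
  - name: "6"
    allcause: {probability: 0.027, shape: 2, lower: 0, upper: 338}
    cause_proportion: 0.204
    differential: B
    high_fraction: 0.5
    high_cap: 112
    n_trials: 50000
    seed: 1006
  - name: "7"
    allcause: {probability: 0.027, shape: 2, lower: 0, upper: 338}
    cause_proportion: 0.139
    differential: A
    high_fraction: 0.5
    high_cap: 112
    n_trials: 50000
    seed: 1007
  - name: "8"
    allcause: {probability: 0.027, shape: 2, lower: 0, upper: 338}
    cause_proportion: 0.139
    differential: B
    high_fraction: 0.5
    high_cap: 112
    n_trials: 50000
    seed: 1008
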