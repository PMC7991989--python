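# Full-pipeline configuration: a 200-woman synthetic cohort under the
# generator's default (realistic-signal) conditions, evaluated over ten
# 70/30 patient-level repetitions.
sim:
  n_patients: 200
  prevalence_drug: 0.3912
  monitoring_days: 56
  seed: 1
input_dir: null
output_dir: out
min_diet_days: 14
outlier_percentile: 0.95
fit_on: all_population
raised_mode: overlapping
alpha: 0.75
cv_folds: 5
selection_rule: min
train_frac: 0.7
n_reps: 10
seed: 5
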