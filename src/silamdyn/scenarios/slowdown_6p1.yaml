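# Global turnover slowdown scenario: disease incorporation is a uniform
# 0.939x of control (a 6.1% slowdown in global average protein turnover),
# with steady-state abundance unchanged.  Cohort design mirrors the
# forebrain experiment: 3 vs 3 mice, 6-day heavy-lysine pulse, three
# detergent fractions, 1392 proteins quantified on both axes.
name: slowdown_6p1
n_proteins: 1392
n_mice: 3
n_fractions: 3
peptides_per_protein: 10
double_k_fraction: 0.2
half_life_median_days: 15.0
half_life_sigma: 0.7
schedule:
  label_days: 6.0
  precursor_plateau: 0.9
  precursor_rise_time: 0.0
noise:
  intensity_cv: 0.10
  missing_rate: 0.05
  observations_per_peptide: {1: 0.2, 2: 0.5, 3: 0.3}
  decoy_pair_rate: 0.02
effects:
  kind: uniform_incorporation_scale
  scale: 0.939
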