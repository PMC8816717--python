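# Global turnover speedup scenario: disease incorporation is a uniform
# 1.157x of control (a 15.7% increase in global average protein
# turnover), abundance unchanged; 721 proteins as in a symptomatic
# knockin cortex experiment.
name: speedup_15p7
n_proteins: 721
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
  scale: 1.157
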