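# Null scenario: the two cohorts share identical kinetics; any protein
# reaching nominal significance is a false positive.  Used for type-I
# calibration of the per-protein tests, hence a single detergent
# fraction: the cross-fraction merge keeps the fraction with the largest
# cohort difference, a selection step that inflates the null rejection
# rate and would confound a calibration measurement of the test itself.
name: "null"
n_proteins: 1000
n_mice: 3
n_fractions: 1
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
effects: null
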