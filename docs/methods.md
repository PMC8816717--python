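# Methods

## The measurement and the model

`silamdyn` analyzes pulsed metabolic labeling experiments in mammals
(SILAM / pulsed SILAC): animals are switched to a diet in which lysine
is replaced by its ¹³C₆ isotopologue (K6) for a labeling window of a
few days, and every tryptic peptide that contains lysine appears in the
mass spectrometer as an ion pair spaced by 6.020129/z Da per labeled
lysine. The relative incorporation

    I = H / (H + L)

of a peptide (heavy over total intensity) measures the fraction of its
parent protein synthesized during the window and is therefore a direct
readout of turnover.

The package models each protein as a one-pool first-order system:
synthesis at rate `s` (intensity units/day), degradation with rate
constant `k` (1/day), steady-state abundance `A = s/k`. During a pulse
of length `t` days with the free-lysine precursor pool at heavy
fraction `q`, the expected incorporation of a single-lysine peptide is

    I(k) = q · (1 − e^(−k t)).

With a finite precursor equilibration time constant `τ` the turnover
term becomes the two-compartment convolution
`1 − (k e^(−t/τ) − (1/τ) e^(−k t)) / (k − 1/τ)`, with the analytic
limit `1 − (1 + k t) e^(−k t)` at `k = 1/τ`. The closed form is
verified in the tests against numerical integration of the labeling
ODE `dH/dt = k (p(t) − H)`.

Assumptions: each cohort is at kinetic steady state during the window
(disease perturbations are modeled as step changes applied long before
labeling); lysines of newly made molecules are labeled independently at
the precursor heavy fraction; the label itself does not perturb
kinetics.

## Pipeline

1. **Peptide incorporation** (`turnover.compute_incorporation`).
   `I = H/(H+L)` per evidence row. Pairs supported by fewer than two
   scans are discarded (double-count rule): in an unlabeled decoy
   sample, single-scan heavy matches occur at the percent level while
   independent double matches occur at the square of that rate, so the
   rule suppresses spurious pairs by two orders of magnitude.
   Double-lysine peptides with a nonzero mixed (HL) species carry
   partially labeled molecules; they are excluded here and reserved for
   the precursor-pool estimator.
2. **Protein aggregation** (`aggregate_to_protein`). Median of peptide
   incorporations per (protein, fraction, mouse) — the median resists
   single-peptide outliers; the arithmetic mean is available. The
   replicate rule then keeps a (protein, fraction) pair only when
   quantified in ≥ 2 of 3 mice in *both* cohorts (parameterized for
   other cohort sizes).
3. **Fraction merge** (`merge_fractions`). Tissue is measured as
   several detergent fractions; the nonredundant per-protein record
   keeps the fraction with the greatest |disease − control| mean
   incorporation difference, ties broken by peptide support then
   fraction name. See *Selection effects* below.
4. **Abundance integration** (`abundance`). A (protein, fraction) LFQ
   cell is trusted only when quantified in every mouse (six of six for
   3 v 3); surviving fractions are averaged per mouse on the intensity
   scale. Abundances are consumed as provided by the upstream
   quantification; no re-normalization is applied.
5. **Cohort statistics** (`dynamics`). Two-tailed two-sample t-tests
   per protein on per-mouse incorporations (turnover axis) and
   integrated intensities (abundance axis); global average protein
   turnover (GAPT) = mean over proteins of the cohort-mean
   incorporation, compared with an unpaired two-sided test across
   per-protein means (paired option available). p-values are nominal;
   Benjamini–Hochberg is deliberately not applied by default.
6. **Mechanism classification** (`classify_mechanism`). At significance
   level α (default 0.01 for the dynaplot, 0.05 for tables): turnover
   and abundance both up → net synthesis increased; both down → net
   synthesis decreased; turnover up with abundance down → net
   degradation increased; turnover down with abundance up → net
   degradation decreased; turnover moved with abundance flat → repair
   flux up/down (a futile synthesis-and-degradation shift); abundance
   moved with turnover flat → net synthesis change, flagged uncoupled.
7. **Precursor-pool control** (`estimate_precursor_pool`). Among newly
   synthesized molecules each lysine is heavy with probability `q`, so
   a 2-lysine peptide's fully heavy and mixed species obey
   HH : HL = q² : 2q(1−q), giving `q̂ = 2·HH/(2·HH + HL)` per record
   (cohort median). The pool estimate is reported as a cohort-balance
   control and feeds only the rate inversion
   `k = −ln(1 − I/q̂)/t` (`fit_rate_constant`); cohort comparisons use
   uncorrected `H/(H+L)`.
8. **Aging trend** (`aging_trend`). Across cohorts at ordered ages, the
   headline statistic is the share of proteins whose incorporation at
   the oldest age is below the youngest, tested with a two-sided sign
   (binomial) test; least-squares slopes over age are reported
   alongside. The endpoint contrast (not the slope sign) is the
   headline because it is the simplest statement of a monotone decline.

## Choice of test statistic

With cohorts of three, the per-protein comparison defaults to the
classical pooled-variance Student t-test (4 degrees of freedom). The
Welch correction, often the safer default at larger n, is available via
`equal_var=False` but is a poor instrument here: its estimated degrees
of freedom collapse toward 2, which both destroys power (simulated
six-regime agreement drops from ~95% to ~70% at 10% intensity CV) and
makes the null conservative (~3.4% rejections at nominal 5%). The
pooled test is calibrated on the simulator's null (5.1% at nominal 5%,
single fraction) and is the textbook test for this design.

## Selection effects of the fraction merge — a measured property

Keeping, per protein, the fraction with the largest cohort difference
is a maximum over noisy contrasts. Two consequences, both reproduced by
the simulator and asserted in the test suite:

- under a true uniform −6.1% global turnover change with three
  fractions and realistic peptide support, the recovered GAPT change is
  inflated to roughly −8%;
- under the null, the per-protein false-positive rate roughly doubles
  (~10% at nominal 5%).

The rule is retained because it defines the pipeline's nonredundant
output, but calibration-style analyses in this package (global-effect
recovery, type-I calibration, parameter recovery) use designs that do
not pass through the selection step: a single fraction for the
global-effect and null scenarios, and all-fraction aggregation for rate
recovery. Interpret merged per-protein effect sizes accordingly.

## The synthetic-data generator

`simulate_cohorts` emulates the study design end to end: two cohorts of
3 mice, a 6-day pulse (8-day variant available), 3 detergent fractions,
and per-protein first-order kinetics. Defaults (all overridable):

| Parameter | Default | Basis |
|---|---|---|
| label window | 6 days | study design |
| precursor plateau `q` | 0.9 | high but incomplete dietary labeling |
| precursor rise time `τ` | 0 days | pool assumed equilibrated; finite τ supported |
| half-life distribution | log-normal, median 15 d, ln-sd 0.7 | matches the observed incorporation dynamic range (~1–70% at 6 d) and the between-protein dispersion implied by reported global-effect statistics |
| abundance distribution | log-normal, median 1e7, ln-sd 1.2 | typical LFQ intensity scales |
| peptides per protein | 10 (first always single-K) | observed quantified-peptide-to-protein ratio ~10 |
| double-lysine share | 20% | missed-cleavage frequency; feeds the pool estimator |
| intensity CV | 10% | typical label-pair quantification noise |
| dropout | 5% per observation | missingness plumbing |
| scans per pair | {1: 0.2, 2: 0.5, 3: 0.3} | exercises the double-count rule |
| decoy pair rate | 2% | empirical spurious-match rate in unlabeled samples |

Effect archetypes place proteins unambiguously in each regime:
(s_ratio, k_ratio) = (3, 1.5) net synthesis up, (1, 2) net degradation
up, (2, 2) repair up, and their reciprocals; repair regimes use exact
powers of two so steady-state abundance is bit-identical between
cohorts in the noise-free limit. `scale_incorporation_truth` instead
injects an exactly uniform relative incorporation change (used for the
−6.1% and +15.7% demo scenarios) while holding abundance fixed.

What the generator does *not* emulate: chromatography, isotope
envelopes and spectral interference (simulation starts at extracted ion
intensities); inter-animal biological variability (all noise is
technical, so real-data power at n = 3 will be lower than simulated);
correlated missingness (dropout is independent, whereas real
missingness is intensity-dependent); amino-acid recycling beyond the
single precursor pool. Passing tests therefore demonstrate correctness
of the computations and calibration under the stated noise model, not
field performance on any particular tissue.

## Numerical choices

- The two-compartment incorporation uses the analytic `k = 1/τ` limit
  within a relative tolerance of 1e-9 of the singularity.
- Zero-variance cohorts (exact in the noise-free limit) give p = 1 when
  the means agree and the smallest positive float with a `degenerate`
  flag when they differ; variance below (1e-12 × mean)² counts as zero.
- Rate inversion at incorporation ≥ q̂ is saturated and returned as NaN
  with a warning, never clipped.
- All tables are written sorted with fixed float precision (8
  significant digits), and figures with a fixed SVG hash salt and no
  date metadata, so identical configurations are byte-identical.
- Merge ties: larger total peptide support, then lexicographic fraction
  id — arbitrary but stable.

## Problem sizes

The committed scenarios use the study-scale proteome sizes (1392, 721
and 1000 proteins); recovery analyses in the tests and the acceptance
script use 100-point rate grids, 1000-protein recovery runs, 20-seed
global-effect sweeps, 50-seed decoy sweeps of 5000 proteins each, and a
360-protein four-age aging series. The whole suite runs in well under a
minute on one core.

## Known limitations

- Relative turnover only: absolute half-lives require the one-pool
  inversion and inherit its assumptions (single precursor pool, steady
  state); the package reports them but the cohort comparisons never
  depend on them.
- The classifier's "uncoupled" net-synthesis calls (abundance moved,
  turnover flat) conflate true synthesis changes with turnover changes
  below detection power.
- The MaxQuant evidence dialect cannot carry the mixed isotopologue of
  2-lysine peptides, so the precursor-pool control is only available
  from native-schema tables.
- With n = 3 per cohort, per-protein power at α = 0.01 is the binding
  constraint on regime recovery (~95% under the stated noise, 100%
  noise-free); smaller effects than the archetype ratios will land in
  "unchanged" or the repair regimes.
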