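# silamdyn

Proteome dynamics from in vivo heavy-lysine (SILAM) labeling: quantify
relative protein turnover, integrate label-free abundance, compare
disease against control cohorts, and classify each protein's change
into one of six mechanistic regimes.

## Who this is for

Groups running pulsed metabolic labeling in mice (or any cohort
design): animals are fed a ¹³C₆-lysine (K6) diet for about a week, and
every lysine-containing tryptic peptide shows up as an ion pair spaced
by 6.02/z Da. The heavy fraction

    I = H / (H + L)

of a peptide measures the share of its protein synthesized during the
labeling window — a direct turnover readout. Under the first-order
model (synthesis `s`, degradation rate constant `k`, steady state
`A = s/k`), the expected incorporation after `t` days with precursor
heavy fraction `q` is `I = q (1 − e^(−k t))`.

Plotting the cohort change in turnover against the change in abundance
separates mechanisms: both up → net synthesis increased; turnover up
with abundance down → net degradation increased; turnover moved with
abundance flat → a change in repair flux (synthesis and degradation
shifted together); and the mirror images. `silamdyn` implements this
whole analysis — the double-count pair filter, the 2-of-3 replicate
rule, the cross-fraction merge, the six-of-six abundance completeness
rule, mouse-wise abundance integration, per-protein and global
(GAPT) t-tests, the regime classifier, a precursor-pool control from
double-lysine peptides, and an aging trend test — plus a forward
simulator with known per-protein kinetics so every stage is verifiable
without raw instrument data.

## Worked example

Run the packaged scenario that injects a uniform 6.1% turnover
slowdown into a 1392-protein, 3 v 3 mouse, 3-fraction experiment:

```sh
$ silamdyn report --scenario slowdown_6p1 --seed 1 --out-dir demo
GAPT change -9.53% (p = 4.04e-06, n = 1392); bundle in demo
```

The bundle contains the simulated evidence and ground truth, every
intermediate table (peptide and protein incorporation, precursor pool,
abundance profiles), per-protein results with mechanism classes, the
dynaplot (SVG + table), and `summary.json` with the filter funnel:
79,397 evidence rows → 51,900 quantified peptide pairs → 1392 proteins
passing the replicate rule.

Note the recovered global change (−9.5%) overshoots the injected
−6.1%: the merge rule that keeps, per protein, the detergent fraction
with the *largest* cohort difference selects on noise and inflates
effect sizes. This is a real property of that filtering scheme which
the simulator makes visible — `docs/methods.md` quantifies it, and the
calibration analyses below use single-fraction designs that bypass it
(where they recover −6.1% within a few tenths of a point).

The decoy benchmark shows why quantification demands pairs observed at
least twice — spurious matches drop from the percent level to the
basis-point level:

```sh
$ silamdyn decoy --seed 1
single-count false pairs: 2.34%  double-count: 0.040%
```

And a simulated aging series (turnover slowing 20% per age step)
recovers a proteome-wide decline:

```sh
$ silamdyn aging --n-proteins 120 --seed 3
100.0% of 120 proteins decreased incorporation with age (sign test p = 1.5e-36)
```

Other subcommands: `simulate`, `validate`, `quantify-turnover`,
`integrate-abundance`, `classify`, `mass-shift`. The same operations
are available as a library (`silamdyn.simulate_cohorts`,
`compute_incorporation`, `compute_gapt`, `classify_mechanism`, ...);
real data enters as TSV evidence/protein-group tables in the native
schema or the MaxQuant evidence dialect with a sample map (see
`silamdyn/io.py` for the column schemas).

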