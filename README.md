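# fluorct

Comparative-Ct qPCR quantification with **variable fluorescence thresholds**,
for stochastic low-input samples — cell-free embryonic blastocoel fluid,
single cells, and anything else where expression is too scattered for a
single threshold to fit every well.

## The problem

Relative qPCR quantification (the comparative Ct / ΔΔCt method) reads every
well's cycle threshold Ct at one fixed fluorescence threshold per gene and
reports double-normalised fold changes. That works when all samples express
within a couple of orders of magnitude of each other. In low-input material
the initial template N0 varies over *many* orders of magnitude: wells cross
any given fluorescence level anywhere between cycle 2 and cycle 40, or never,
and no single threshold intersects every well's exponential phase. Bench
practice then reads each well at its own threshold Ft — but plain ΔΔCt
arithmetic on thresholds that differ per well is wrong.

## The method

Under exponential amplification, fluorescence follows

    F(c) = k · N0 · E^c

with k an assay-specific fluorescence-per-copy constant and E the per-cycle
efficiency (E = 2 under the standard perfect-doubling assumption), so a well
read at threshold Ft has Ft = k · N0 · E^Ct. Two consequences:

**Threshold consolidation.** A (Ct, Ft) pair can be re-expressed at any other
threshold without re-running the instrument:

    Ct_new = Ct + log_E(Ft_new / Ft)

After consolidating each gene onto one (arbitrary) common threshold, ordinary
comparative-Ct arithmetic applies: ΔCt = Ct(target) − Ct(control) within a
sample, ΔΔCt = ΔCt(S1) − ΔCt(S2) between samples, fold change = E^(−ΔΔCt).

**The fluorescence coefficient.** Equivalently, fold changes can be computed
directly from raw, unconsolidated records; the variable thresholds contribute
a multiplicative coefficient in front of the usual term:

    (N0_tar,S1/N0_ctrl,S1) / (N0_tar,S2/N0_ctrl,S2)
        = (Ft_tar,S1/Ft_ctrl,S1) · (Ft_ctrl,S2/Ft_tar,S2) · E^(−ΔΔCt)

The two routes are algebraically identical; the package implements both and
tests them against each other. Pairwise Ct differences within a gene are
invariant to the consolidated threshold's value, and all pairwise
expression ratios are invariant to the choice of reference sample. Wells
that never amplify are categorical ("not expressed"), never extrapolated to
a Ct or reported as ratio 0.

## Worked example

Simulate a small plate (one target gene plus an endogenous control across six
samples, template drawn log-uniformly over many decades, per-well noise,
dropout) and run the full workflow:

```sh
fluorct simulate --n-samples 6 --n-targets 1 --seed 42 \
        --out-curves curves.csv --out-truth truth.csv
fluorct run --curves curves.csv --out-dir results --control ControlGene
```

The log (stderr) names the resolved per-gene thresholds, the reference
sample, and every excluded well:

```
WARNING well (Sample03, Target01) excluded: ... curve rises too early for automatic baseline correction
INFO consolidation: gene ControlGene -> threshold 6826.24 RFU
INFO consolidation: gene Target01 -> threshold 2859.32 RFU
INFO quantification: gene Target01 reference sample Sample02 (4 expressed, 0 not expressed, 1 not normalizable)
```

`results/fold_change.csv` then holds the relative expression of every
expressed sample versus the (automatically chosen, highest-expressing)
reference:

```
sample,fold_change_ratio,log10_fold_change
Sample01,0.0168,-1.77
Sample02,1.00,0.00
Sample04,0.0611,-1.21
Sample05,2.72E-09,-8.57
```

Read: Sample02 expresses the target most (reference, ratio 1); Sample01
expresses about 60× less; Sample05 about nine orders of magnitude less —
a spread far beyond what a fixed-threshold analysis could quantify, yet
still an *expressing* sample, distinct from Sample06 whose control gene
never amplified (excluded as not normalizable, not reported as zero).
Against the simulation's ground truth, Sample05's true normalised ratio is
1.8e-9 versus the estimated 2.7e-9 — within the accuracy expected under
per-well read noise.

The same analysis can start from an instrument-exported Ct table instead of
raw curves (`fluorct run --ct-table ...`), and the stages are available
individually as `fluorct callct`, `fluorct consolidate` (with explicit
`--threshold GENE=VALUE` overrides) and `fluorct quantify`. Everything is
also a plain library call: see `fluorct.consolidate_table`,
`fluorct.fold_change_report`, `fluorct.recovery_experiment`.

## Layout

- `src/fluorct/io.py` — CSV interchange (Ct tables, curve exports, reports)
- `src/fluorct/curves.py` — baseline correction, amplification detection,
  automatic threshold placement, fractional Ct interpolation
- `src/fluorct/consolidate.py` — threshold consolidation
- `src/fluorct/quantify.py` — ΔCt / ΔΔCt / fold-change reports
- `src/fluorct/simulate.py` — seedable stochastic plate simulator with
  ground truth, and recovery experiments
- `src/fluorct/cli.py` — the `fluorct` command
- `docs/methods.md` — model, assumptions, numerical choices, limitations
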