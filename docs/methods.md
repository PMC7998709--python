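# Methods

## Model

All quantification rests on the exponential amplification model
F(c) = k·N0·E^c: fluorescence F at cycle c is proportional (constant k,
assay-specific, in RFU per copy unit) to the amount of product, which
multiplies by the efficiency E each cycle from the initial template N0.
Reading a well at fluorescence threshold Ft defines the cycle threshold Ct
through Ft = k·N0·E^Ct; Ct is fractional by construction. E defaults to 2
(perfect doubling) everywhere — consolidation, ΔΔCt, and fold changes all
accept other values of E > 1, but a single global E is applied per analysis;
per-well efficiency estimation is out of scope.

Two normalisations produce the reported quantity. Within a sample,
ΔCt = Ct(target) − Ct(control) removes the sample's overall template load
using an endogenous control gene (exactly one control gene per analysis).
Between samples, ΔΔCt = ΔCt(S1) − ΔCt(S2) and the fold change is E^(−ΔΔCt).
This arithmetic presumes all Ct values of a gene were read at one
threshold. When they were not, either (a) every record is first
*consolidated* to a common per-gene threshold via
Ct_new = Ct + log_E(Ft_new/Ft), or (b) the fold change is computed from raw
records with the fluorescence coefficient
(Ft_tar,S1/Ft_ctrl,S1)·(Ft_ctrl,S2/Ft_tar,S2) multiplying E^(−ΔΔCt). The
two routes are the same identity rearranged; the test suite checks their
agreement to 1e-9 relative over randomised inputs, and `delta_ct_table`
refuses mixed-threshold input outright so route (a) cannot be skipped by
accident.

The consolidated threshold's value is arbitrary — pairwise Ct differences
within a gene are invariant to it — but must be singular per gene.
Consolidation is per gene, never across genes: cross-gene threshold ratios
cancel only inside the double normalisation. AUTO threshold resolution uses
the geometric mean of the gene's observed thresholds, which minimises the
worst-case log-distance any record is moved. A consolidated Ct may be ≤ 0
(virtual crossing before cycle 1) when the target threshold sits far below
the original; records parsed from instrument exports must still have
Ct > 0.

Undetected wells ("Undetermined" in exports) are a category, not a number:
they pass through consolidation untouched, make a sample "not expressed"
(target) or "not normalizable" (control), and are reported in a separate
report section with NA — never as ratio 0, and never extrapolated.

## Curve analysis

Raw curves are processed in four steps, each a deterministic rule so a
pipeline needs no per-well human input (the error paths below are exactly
the wells where a human would intervene):

1. **Baseline correction** subtracts the mean fluorescence over cycles 3–15
   (default), truncated to end two cycles before the detected rise of
   amplification. The rise is the first cycle from which the curve stays
   above 10% of its dynamic range (measured above the curve minimum so a
   constant offset is not a rise); a curve whose whole range is under 20
   median absolute deviations of itself has no rise at all. The 20-MAD gate
   separates two well-separated populations: pure read noise spans ~7 MADs,
   while genuinely amplified curves span tens to thousands. Without the
   gate, noise wiggle registers as an "early rise" and noise-only wells
   error out instead of reading undetected; with a much larger gate,
   early-saturating wells under heavy noise are misread as structureless
   and their baseline windows swallow amplification signal. Fewer than
   3 cycles of usable window is a baseline error: the curve rises too early
   for automatic handling and needs a manual window or threshold.
2. **Amplification detection**: a well amplified iff its peak corrected
   fluorescence exceeds noise_k (default 10) baseline standard deviations
   and the last five cycles average above the first five. On 1000 simulated
   noise-only wells the false-positive rate is below 1%.
3. **Threshold selection** places the per-well threshold at the geometric
   mean of the noise ceiling (noise_k × baseline sd, sd floored at 1 RFU)
   and the plateau floor (90% of peak corrected fluorescence) — the
   log-domain midpoint of the exponential phase, automating the manual
   per-well adjustment of bench practice with a reproducible rule. The
   curve must cross the chosen threshold exactly once from below;
   otherwise a threshold error instructs manual override.
4. **Ct interpolation** is log-linear between the bracketing cycles
   (exact under the exponential model); if the lower bracket is
   nonpositive the code falls back to linear interpolation in raw
   fluorescence and logs the fact. Cycles are 1-based and Ct is reported
   on the instrument's cycle axis.

No curve smoothing is applied; a non-monotone exponential phase is
surfaced as an error rather than silently smoothed away.

## The simulator

`simulate_curve` generates F(c) = baseline + x_c/(1 + x_c/plateau) + ε_c
with x_c = k·N0·E^c and ε_c independent Gaussian per cycle. The logistic
saturation is the simplest monotone form with an exponential early phase
and a plateau; `plateau = inf` recovers the pure exponential. N0 is drawn
log-uniformly per well (maximum-ignorance across orders of magnitude),
with a per-well dropout probability of true zeros. Default plate:
16 samples × 94 genes (one endogenous control plus an apoptosis-panel-sized
target block), plateaus 3e4–1.2e5 RFU, per-well noise sd log-uniform
1–300 RFU, baselines 0–500 RFU, targets spanning 10^-10–10^3.5 copy units
and the control 10^-4–10^2 (steady per-cell expression, variable lysed-cell
load). Under these defaults the called wells span cycle thresholds from
below 5 (counting the abundant-template wells the automatic pipeline flags
for manual reading) to above 38, with selected thresholds over more than
three decades — the regime in which no single threshold can serve.

All randomness flows from the single `PlateSpec.seed`. Ground truth keeps
every N0 so `recovery_experiment` can score the entire pipeline:
simulate → call → consolidate → quantify → join estimated to true fold
changes per well, propagating per-well failures as exclusions rather than
aborting.

What the simulator does **not** emulate, so what passing recovery tests do
not show: efficiency drift between wells or cycles (E is exactly shared),
autocorrelated or multiplicative noise, reverse-transcription variability,
primer-dimer and multi-peak artifacts, and inter-plate effects. Recovery
accuracy on simulated plates bounds algorithmic error, not assay error.

Two standing validation designs are packaged: `dynamic_range_plate`
(noiseless, saturation-free; target template falls a decade per sample as
control rises one, walking the true normalised ratio across 10^14 — the
full pipeline recovers it to |log10 error| < 0.05, and to ~1e-5 in
practice) and `noisy_validation_plate` (200 wells, read noise at 1% of
plateau; the median |log10 error| of recovered fold changes is ~0.1; the
0.15 bound asserted in the tests is a calibration constant of this
harness, not an external claim). Estimator bias under noise is measured
and reported by the experiment, not assumed zero — the dominant systematic
term is saturation: per-well thresholds placed at a few tens of percent of
the plateau compress Ct differences slightly, and the effect largely
cancels between wells read at similar relative heights.

## Reporting

Fold changes are reported against one reference sample; AUTO picks the
highest-expressing sample (smallest ΔCt, ties broken lexicographically).
The choice is cosmetic: all pairwise ratios are invariant to it (tested to
1e-9 relative). The log column is base 10 — the bundled published example
table is consistent with log10 within its printed rounding for 17 of 18
rows (the remaining row's printed ratio and printed log disagree by 0.02
in the log, an inconsistency in the source table that the test suite
records by failing on exactly that row). Ratios print at 3 significant
figures, switching to scientific notation below 0.01; logs print at 2
decimals.

## Interchange formats

Plain UTF-8 CSV only: `sample,gene,role,ct,ft` for Ct tables (ct may be
`Undetermined` in any capitalisation, or empty, with ft then absent),
`sample,gene,cycle,fluorescence` for long-format curve exports (cycles
contiguous from 1 per well after sorting), and
`sample,fold_change_ratio,log10_fold_change` for reports. Parsing is
locale-strict (decimal point only; grouping characters are errors), and a
written Ct table reads back to identical records. RDML and proprietary
instrument formats are out of scope.

## Known limitations

- Accuracy degrades when the baseline window is contaminated: template
  abundant enough to rise before cycle ~6 cannot be called automatically
  (by design, it errors), and noise above a few percent of the plateau
  inflates both thresholds and their saturation bias.
- The fixed-E assumption is inherited from comparative Ct itself; with
  real efficiencies below 2 all log fold changes scale accordingly.
- One control gene; multi-control geometric-mean normalisation is not
  implemented.
- No statistical uncertainty is attached to reported ratios; the package
  reports point estimates only.
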