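"""Amplification-curve analysis: from raw fluorescence to (Ct, Ft) records.

The underlying model is exponential amplification, F(c) = k·N0·E^c, where
k converts template copies to fluorescence, N0 is the initial template and
E the per-cycle amplification efficiency (2 under the standard perfect-
doubling assumption).  Reading a curve at a fluorescence threshold Ft gives
the (fractional) cycle threshold Ct = log_E(Ft / (k·N0)).

Real instruments report a baseline offset, noise, and a late-cycle plateau,
so the steps here are: baseline-correct, decide whether the well amplified
at all, place a per-well fluorescence threshold inside the exponential
phase, and interpolate the fractional crossing cycle.  Each well gets its
own threshold — the point of the downstream consolidation step is that this
is harmless.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as _dc_replace
from typing import Iterable, Literal

import numpy as np

from .io import CtRecord, CurveSet

__all__ = [
    "AmplificationCurve",
    "ThresholdWindow",
    "BaselineError",
    "ThresholdError",
    "baseline_correct",
    "detect_amplification",
    "select_threshold",
    "call_ct",
    "iter_curves",
    "process_curves",
]

logger = logging.getLogger(__name__)

#: default cycles used to estimate the baseline (truncated if the rise is early)
DEFAULT_BASELINE_WINDOW = (3, 15)
#: multiplier separating amplification signal from baseline noise
DEFAULT_NOISE_K = 10.0
#: fraction of the maximum corrected fluorescence taken as the plateau floor
DEFAULT_PLATEAU_FRACTION = 0.9


class BaselineError(ValueError):
    """The baseline window cannot be established (curve rises too early)."""


class ThresholdError(ValueError):
    """No valid automatic fluorescence threshold exists for this curve."""


@dataclass(frozen=True)
class AmplificationCurve:
    """Ordered per-cycle fluorescence readings for one well (cycles 1..C)."""

    sample_id: str
    gene_id: str
    fluorescence: np.ndarray
    baseline_corrected: bool = False
    baseline_window: tuple[int, int] | None = None
    baseline_sd: float | None = None

    def __post_init__(self):
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "fluorescence", f)
        if f.ndim != 1 or f.size < 10:
            raise ValueError(
                f"well ({self.sample_id}, {self.gene_id}): a curve needs at "
                f"least 10 cycles, got {f.size}"
            )
        if not np.all(np.isfinite(f)):
            raise ValueError(
                f"well ({self.sample_id}, {self.gene_id}): non-finite fluorescence"
            )

    @property
    def n_cycles(self) -> int:
        return int(self.fluorescence.size)

    def value(self, cycle: int) -> float:
        """Fluorescence at a 1-based cycle index."""
        if not 1 <= cycle <= self.n_cycles:
            raise IndexError(f"cycle {cycle} outside 1..{self.n_cycles}")
        return float(self.fluorescence[cycle - 1])


@dataclass(frozen=True)
class ThresholdWindow:
    """The fluorescence band and cycle span bracketing the exponential phase."""

    noise_ceiling: float
    plateau_floor: float
    exp_start_cycle: int
    exp_end_cycle: int

    def __post_init__(self):
        if not self.noise_ceiling < self.plateau_floor:
            raise ValueError("noise_ceiling must be below plateau_floor")
        if not self.exp_start_cycle < self.exp_end_cycle:
            raise ValueError("exp_start_cycle must precede exp_end_cycle")


def _rise_cycle(f: np.ndarray) -> int | None:
    """First 1-based cycle from which the curve has risen for good.

    The rise level is 10% of the curve's dynamic range above its minimum
    (measured from the minimum so a constant baseline offset is not a
    rise); the rise cycle is the first cycle after the last excursion
    below that level, i.e. the exceedance must be sustained.  A curve
    whose range is within noise wiggle (under 20 median absolute
    deviations — pure noise spans ~7 MADs, amplified curves tens to
    thousands) has no rise at all, so baseline noise itself cannot
    masquerade as an early rise.
    """
    lo = float(f.min())
    span = float(f.max()) - lo
    if span <= 0:
        return None
    mad = float(np.median(np.abs(f - np.median(f))))
    if span <= 20.0 * mad:
        return None
    level = lo + 0.1 * span
    below = np.nonzero(f <= level)[0]
    if below.size == 0:
        return 1
    rise = int(below[-1]) + 2  # 1-based cycle after the last sub-level cycle
    return rise if rise <= f.size else None


def baseline_correct(
    curve: AmplificationCurve, window: tuple[int, int] | None = None
) -> AmplificationCurve:
    """Subtract the mean early-cycle background fluorescence.

    With no explicit ``window`` the default cycles 3–15 are used, truncated
    to end two cycles before the detected rise of amplification if that is
    earlier.  The window's standard deviation is retained on the returned
    curve — it is the noise scale used for amplification detection and
    threshold placement.

    Raises :class:`BaselineError` if fewer than 3 cycles remain: such a
    curve rises too early for automatic handling.
    """
    f = curve.fluorescence
    if window is None:
        start, end = DEFAULT_BASELINE_WINDOW
        end = min(end, curve.n_cycles)
        rise = _rise_cycle(f)
        if rise is not None:
            end = min(end, rise - 2)
    else:
        start, end = window
        if not (1 <= start <= end <= curve.n_cycles):
            raise BaselineError(
                f"window {window} outside cycles 1..{curve.n_cycles}"
            )
    if end - start + 1 < 3:
        raise BaselineError(
            f"well ({curve.sample_id}, {curve.gene_id}): baseline window "
            f"({start}, {end}) shorter than 3 cycles — curve rises too early "
            "for automatic baseline correction"
        )
    segment = f[start - 1 : end]
    mean = float(segment.mean())
    sd = float(segment.std(ddof=0))
    return _dc_replace(
        curve,
        fluorescence=f - mean,
        baseline_corrected=True,
        baseline_window=(start, end),
        baseline_sd=sd,
    )


def _require_corrected(curve: AmplificationCurve) -> None:
    if not curve.baseline_corrected or curve.baseline_sd is None:
        raise ValueError("operation requires a baseline-corrected curve")


def detect_amplification(curve: AmplificationCurve, noise_k: float = DEFAULT_NOISE_K) -> bool:
    """Did this well amplify at all?

    True iff the peak corrected fluorescence exceeds ``noise_k`` baseline
    standard deviations AND the last five cycles average higher than the
    first five (the curve actually rose rather than spiked).
    """
    _require_corrected(curve)
    f = curve.fluorescence
    if not f.max() > noise_k * curve.baseline_sd:
        return False
    return float(f[-5:].mean()) > float(f[:5].mean())


def select_threshold(
    curve: AmplificationCurve,
    noise_k: float = DEFAULT_NOISE_K,
    plateau_fraction: float = DEFAULT_PLATEAU_FRACTION,
) -> tuple[float, ThresholdWindow]:
    """Automatically place a per-well fluorescence threshold.

    The threshold is the geometric mean of the noise ceiling
    (``noise_k`` × baseline sd, with the sd floored at 1 RFU) and the
    plateau floor (``plateau_fraction`` of the peak corrected
    fluorescence) — i.e. the log-domain midpoint of the exponential phase.
    This automates the manual per-well threshold adjustment of bench
    practice with a deterministic rule.

    Raises :class:`ThresholdError` if the curve does not cross the chosen
    threshold exactly once from below (a non-monotone exponential phase
    needs a manual override).
    """
    if not detect_amplification(curve, noise_k):
        raise ValueError(
            f"well ({curve.sample_id}, {curve.gene_id}): no amplification "
            "detected; a fluorescence threshold is undefined"
        )
    f = curve.fluorescence
    noise_ceiling = noise_k * max(curve.baseline_sd, 1.0)
    plateau_floor = plateau_fraction * float(f.max())
    if not noise_ceiling < plateau_floor:
        raise ThresholdError(
            f"well ({curve.sample_id}, {curve.gene_id}): noise ceiling "
            f"{noise_ceiling:.3g} reaches the plateau floor {plateau_floor:.3g}; "
            "set the threshold manually"
        )
    ft = math.sqrt(noise_ceiling * plateau_floor)

    upward = np.nonzero((f[:-1] < ft) & (f[1:] >= ft))[0]
    if upward.size != 1:
        raise ThresholdError(
            f"well ({curve.sample_id}, {curve.gene_id}): curve crosses the "
            f"automatic threshold {ft:.3g} {upward.size} times; set the "
            "threshold manually"
        )

    exp_start = int(np.nonzero(f > noise_ceiling)[0][0]) + 1
    exp_end = int(np.nonzero(f >= plateau_floor)[0][0]) + 1
    if not exp_start < exp_end:
        raise ThresholdError(
            f"well ({curve.sample_id}, {curve.gene_id}): exponential phase "
            "too short to bracket; set the threshold manually"
        )
    return ft, ThresholdWindow(noise_ceiling, plateau_floor, exp_start, exp_end)


def call_ct(
    curve: AmplificationCurve,
    ft: float,
    role: str = "target",
    interpolation: Literal["log", "linear"] = "log",
) -> CtRecord:
    """Read the fractional cycle threshold of a corrected curve at ``ft``.

    If the curve never reaches ``ft`` the record is undetected.  Otherwise,
    with c the last cycle satisfying F(c) < ft ≤ F(c+1),

        Ct = c + (log F_t − log F(c)) / (log F(c+1) − log F(c))

    — log-linear interpolation, exact under exponential growth.  If F(c) is
    nonpositive at the bracket (or ``interpolation="linear"``), plain linear
    interpolation in raw fluorescence is used instead.
    """
    _require_corrected(curve)
    if not ft > 0:
        raise ValueError(f"ft must be > 0, got {ft}")
    f = curve.fluorescence
    if float(f.max()) < ft:
        return CtRecord.undetected(curve.sample_id, curve.gene_id, role)

    brackets = np.nonzero((f[:-1] < ft) & (f[1:] >= ft))[0]
    if brackets.size == 0:
        raise ThresholdError(
            f"well ({curve.sample_id}, {curve.gene_id}): fluorescence is "
            f"already at or above {ft:.3g} at cycle 1; Ct cannot be interpolated"
        )
    i = int(brackets[-1])  # last upward crossing
    c = i + 1  # 1-based cycle of the lower bracket
    lo, hi = float(f[i]), float(f[i + 1])
    if interpolation == "linear" or lo <= 0:
        if interpolation != "linear":
            logger.warning(
                "well (%s, %s): nonpositive fluorescence %.3g at the crossing "
                "bracket; falling back to linear interpolation",
                curve.sample_id,
                curve.gene_id,
                lo,
            )
        ct = c + (ft - lo) / (hi - lo)
    else:
        ct = c + (math.log(ft) - math.log(lo)) / (math.log(hi) - math.log(lo))
    return CtRecord(curve.sample_id, curve.gene_id, role, ct=float(ct), ft=float(ft))


# ---------------------------------------------------------------------------
# whole-plate driver


def iter_curves(curve_set: CurveSet) -> Iterable[AmplificationCurve]:
    for (sample, gene), values in curve_set:
        yield AmplificationCurve(sample, gene, values)


def process_curves(
    curve_set: CurveSet,
    control_gene: str | None = None,
    *,
    baseline_window: tuple[int, int] | None = None,
    noise_k: float = DEFAULT_NOISE_K,
    plateau_fraction: float = DEFAULT_PLATEAU_FRACTION,
    interpolation: Literal["log", "linear"] = "log",
    on_error: Literal["raise", "skip"] = "raise",
) -> list[CtRecord]:
    """Run baseline → detection → threshold → Ct for every well.

    Wells that do not amplify become undetected records.  Wells that fail a
    step (early rise, ambiguous threshold) either abort the run
    (``on_error="raise"``) or are logged and dropped (``"skip"``), so one
    pathological well need not sink a plate.
    """
    records: list[CtRecord] = []
    for curve in iter_curves(curve_set):
        role = "control" if curve.gene_id == control_gene else "target"
        try:
            corrected = baseline_correct(curve, baseline_window)
            if not detect_amplification(corrected, noise_k):
                records.append(
                    CtRecord.undetected(curve.sample_id, curve.gene_id, role)
                )
                continue
            ft, _ = select_threshold(corrected, noise_k, plateau_fraction)
            records.append(call_ct(corrected, ft, role, interpolation))
        except (BaselineError, ThresholdError) as err:
            if on_error == "raise":
                raise
            logger.warning(
                "well (%s, %s) excluded: %s", curve.sample_id, curve.gene_id, err
            )
    return records
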