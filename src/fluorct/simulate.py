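"""Seedable simulator of stochastic low-template qPCR plates.

Emulates the regime of cell-free embryonic blastocoel fluid: per-well
initial template N0 spread over many orders of magnitude (drawn
log-uniformly), outright dropout (N0 = 0), per-cycle Gaussian read noise,
a baseline offset, and late-cycle saturation.  The noiseless well model is

    F(c) = baseline + x_c / (1 + x_c / plateau),    x_c = k · N0 · E^c,

i.e. exponential growth k·N0·E^c early on, rolling over logistically into
a plateau as reagents deplete.  Ground truth (every N0, hence every true
normalised fold change) is retained so the whole pipeline — curve calling,
threshold consolidation, comparative Ct — can be scored against it.

All randomness flows from the single seed in :class:`PlateSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .consolidate import AUTO, ConsolidationSpec, consolidate_table
from .curves import AmplificationCurve, process_curves
from .io import CurveSet
from .quantify import EmptyReportError, delta_ct_table, fold_change_report

__all__ = [
    "WellModelParams",
    "GeneSpec",
    "PlateSpec",
    "GroundTruth",
    "simulate_curve",
    "simulate_plate",
    "recovery_experiment",
    "default_panel",
    "dynamic_range_plate",
    "noisy_validation_plate",
]


@dataclass(frozen=True)
class WellModelParams:
    """Physical parameters of one simulated well.

    n0 is in arbitrary copy units (0 = a true non-expressing well); k
    converts copies to RFU; efficiency is the fold-amplification per cycle;
    plateau caps the accumulated signal (``math.inf`` disables saturation);
    noise_sd is the per-cycle additive Gaussian read noise.
    """

    n0: float
    k: float = 1.0
    efficiency: float = 2.0
    plateau: float = 1e5
    baseline: float = 0.0
    noise_sd: float = 0.0
    n_cycles: int = 40

    def __post_init__(self):
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")
        if not self.k > 0:
            raise ValueError("k must be > 0")
        if not 1 < self.efficiency <= 2:
            raise ValueError("efficiency must be in (1, 2]")
        if not self.plateau > 0:
            raise ValueError("plateau must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cycles < 10:
            raise ValueError("n_cycles must be >= 10")


def simulate_curve(
    params: WellModelParams,
    rng: np.random.Generator | None = None,
    sample_id: str = "S",
    gene_id: str = "G",
) -> AmplificationCurve:
    """Generate one amplification curve under the saturating exponential model."""
    cycles = np.arange(1, params.n_cycles + 1, dtype=float)
    if params.n0 == 0:
        signal = np.zeros_like(cycles)
    elif math.isinf(params.plateau):
        signal = params.k * params.n0 * np.power(params.efficiency, cycles)
    else:
        x = params.k * params.n0 * np.power(params.efficiency, cycles)
        with np.errstate(over="ignore"):
            signal = np.where(np.isinf(x), params.plateau, x / (1.0 + x / params.plateau))
    f = params.baseline + signal
    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        f = f + rng.normal(0.0, params.noise_sd, size=f.shape)
    return AmplificationCurve(sample_id, gene_id, f)


@dataclass(frozen=True)
class GeneSpec:
    """Per-gene simulation settings.

    ``log10_n0_range`` spans the orders of magnitude over which this gene's
    initial template is drawn (log-uniform).  Defaults reproduce the
    observed blastocoel-fluid spread: cycle thresholds covering essentially
    2–40 and selected fluorescence thresholds over several decades.
    """

    gene_id: str
    k: float = 1.0
    is_control: bool = False
    log10_n0_range: tuple[float, float] = (-10.0, 3.5)


def default_panel(n_targets: int = 93) -> list[GeneSpec]:
    """A control gene plus an apoptosis-panel-sized block of targets.

    The control gene varies over fewer decades than the targets: its
    expression level per cell is steady, but the amount of template still
    tracks how many cells lysed into the fluid.
    """
    panel = [GeneSpec("ControlGene", is_control=True, log10_n0_range=(-4.0, 2.0))]
    panel += [GeneSpec(f"Target{i:02d}") for i in range(1, n_targets + 1)]
    return panel


@dataclass(frozen=True)
class PlateSpec:
    """Full plate description; a fixed seed gives an identical plate.

    Per-well noise_sd is drawn log-uniformly over ``noise_sd_range``;
    plateau and baseline uniformly over their ranges.  ``dropout_probability``
    is the chance any given well holds no template at all (n0 = 0).
    ``n0_overrides`` pins exact n0 values for chosen (sample, gene) wells —
    used for designed recovery experiments.
    """

    n_samples: int = 16
    genes: tuple[GeneSpec, ...] = field(default_factory=lambda: tuple(default_panel()))
    dropout_probability: float = 0.15
    noise_sd_range: tuple[float, float] = (1.0, 300.0)
    plateau_range: tuple[float, float] = (3e4, 1.2e5)
    baseline_range: tuple[float, float] = (0.0, 500.0)
    efficiency: float = 2.0
    n_cycles: int = 40
    seed: int = 0
    n0_overrides: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        controls = [g for g in self.genes if g.is_control]
        if len(controls) != 1:
            raise ValueError(f"exactly one control gene required, got {len(controls)}")
        if not 0 <= self.dropout_probability <= 1:
            raise ValueError("dropout_probability must be in [0, 1]")
        if not self.efficiency > 1:
            raise ValueError("efficiency must be > 1")

    @property
    def control_gene(self) -> str:
        return next(g.gene_id for g in self.genes if g.is_control)

    def sample_ids(self) -> list[str]:
        return [f"Sample{i + 1:02d}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class GroundTruth:
    """True initial template per well, and the fold changes derived from it."""

    n0: pd.DataFrame  # columns: sample, gene, n0
    control_gene: str

    def n0_of(self, sample_id: str, gene_id: str) -> float:
        sel = self.n0[(self.n0["sample"] == sample_id) & (self.n0["gene"] == gene_id)]
        if len(sel) != 1:
            raise KeyError((sample_id, gene_id))
        return float(sel["n0"].iloc[0])

    def normalized_expression(self, sample_id: str, gene_id: str) -> float | None:
        """True N0(target)/N0(control) within one sample; None if undefined."""
        tar = self.n0_of(sample_id, gene_id)
        ctrl = self.n0_of(sample_id, self.control_gene)
        if tar == 0 or ctrl == 0:
            return None
        return tar / ctrl

    def fold_change(self, sample_1: str, sample_2: str, gene_id: str) -> float | None:
        """True normalised fold change of sample 1 over sample 2; self → 1."""
        r1 = self.normalized_expression(sample_1, gene_id)
        r2 = self.normalized_expression(sample_2, gene_id)
        if r1 is None or r2 is None:
            return None
        return r1 / r2


def dynamic_range_plate(seed: int = 0) -> PlateSpec:
    """Noiseless two-gene plate whose true normalised ratios span 14 decades.

    Eight samples; target template falls by one decade per sample while the
    control rises by one, so the normalised expression ratio walks from
    10^7 down to 10^-7 — a 10^14 spread, far beyond what any single
    fluorescence threshold could cover.  No noise and no saturation, the
    regime in which the pipeline is exact up to interpolation error.
    """
    genes = (
        GeneSpec("C", is_control=True, log10_n0_range=(-2.0, 1.0)),
        GeneSpec("T", log10_n0_range=(-5.0, 1.0)),
    )
    overrides = {}
    for i in range(8):
        overrides[(f"Sample{i + 1:02d}", "T")] = 10.0 ** (2 - i)
        overrides[(f"Sample{i + 1:02d}", "C")] = 10.0 ** (-5 + i)
    return PlateSpec(
        n_samples=8,
        genes=genes,
        dropout_probability=0.0,
        noise_sd_range=(0.0, 0.0),
        plateau_range=(math.inf, math.inf),
        baseline_range=(0.0, 0.0),
        seed=seed,
        n0_overrides=overrides,
    )


def noisy_validation_plate(seed: int = 1, n_samples: int = 100) -> PlateSpec:
    """Two genes × ``n_samples`` wells with per-cycle noise at 1% of plateau.

    The 200-well default is the standing design for measuring estimator
    error under realistic read noise (sd 1000 RFU against a 10^5 RFU
    plateau), with template spread over several decades and no dropout so
    every well contributes an error measurement.
    """
    return PlateSpec(
        n_samples=n_samples,
        genes=(
            GeneSpec("C", is_control=True, log10_n0_range=(-2.0, 1.0)),
            GeneSpec("T", log10_n0_range=(-4.0, 1.0)),
        ),
        dropout_probability=0.0,
        noise_sd_range=(1000.0, 1000.0),
        plateau_range=(1e5, 1e5),
        baseline_range=(0.0, 300.0),
        seed=seed,
    )


def _uniform(rng: np.random.Generator, low: float, high: float) -> float:
    # degenerate bounds (incl. infinity, for no-saturation regimes) short-circuit
    if low == high:
        return float(low)
    return float(rng.uniform(low, high))


def _log_uniform(rng: np.random.Generator, low: float, high: float) -> float:
    if low == high:
        return float(low)
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def simulate_plate(spec: PlateSpec) -> tuple[CurveSet, GroundTruth]:
    """Simulate one curve per (sample, gene) with full ground truth."""
    rng = np.random.default_rng(spec.seed)
    overrides = dict(spec.n0_overrides or {})
    curves: dict[tuple[str, str], np.ndarray] = {}
    truth_rows = []
    for sample in spec.sample_ids():
        for gene in spec.genes:
            # draw in a fixed order so the stream is reproducible
            dropped = rng.random() < spec.dropout_probability
            lo, hi = gene.log10_n0_range
            n0 = 0.0 if dropped else float(10.0 ** rng.uniform(lo, hi))
            noise_sd = _log_uniform(rng, *spec.noise_sd_range)
            plateau = _uniform(rng, *spec.plateau_range)
            baseline = _uniform(rng, *spec.baseline_range)
            if (sample, gene.gene_id) in overrides:
                n0 = float(overrides[(sample, gene.gene_id)])
            params = WellModelParams(
                n0=n0,
                k=gene.k,
                efficiency=spec.efficiency,
                plateau=plateau,
                baseline=baseline,
                noise_sd=noise_sd,
                n_cycles=spec.n_cycles,
            )
            curve = simulate_curve(params, rng, sample, gene.gene_id)
            curves[(sample, gene.gene_id)] = curve.fluorescence
            truth_rows.append((sample, gene.gene_id, n0))
    truth = GroundTruth(
        n0=pd.DataFrame(truth_rows, columns=["sample", "gene", "n0"]),
        control_gene=spec.control_gene,
    )
    return CurveSet(curves), truth


def recovery_experiment(
    spec: PlateSpec,
    *,
    baseline_window: tuple[int, int] | None = None,
    noise_k: float = 10.0,
    plateau_fraction: float = 0.9,
    reference: str = AUTO,
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a plate, run the full pipeline, and score it against truth.

    Returns one row per (gene, expressed sample) with the true and
    estimated fold change versus the report's reference sample, the
    relative error, and the signed log10 error.  Wells the pipeline cannot
    process are dropped per-well, not fatally.
    """
    curve_set, truth = simulate_plate(spec)
    records = process_curves(
        curve_set,
        control_gene=spec.control_gene,
        baseline_window=baseline_window,
        noise_k=noise_k,
        plateau_fraction=plateau_fraction,
        on_error="skip",
    )
    consolidated = consolidate_table(
        records,
        ConsolidationSpec(efficiency=spec.efficiency, thresholds=dict(thresholds or {})),
    )
    table = delta_ct_table(consolidated, control_gene=spec.control_gene)

    rows = []
    for gene in table.target_genes:
        try:
            report = fold_change_report(table, gene=gene, reference=reference)
        except (EmptyReportError, ValueError):
            continue
        for row in report.rows:
            true_fc = truth.fold_change(row.sample_id, report.reference_sample_id, gene)
            if true_fc is None:
                continue  # spurious call on a zero-template well
            est = row.fold_change_ratio
            rows.append(
                (
                    gene,
                    row.sample_id,
                    report.reference_sample_id,
                    true_fc,
                    est,
                    est / true_fc - 1.0,
                    math.log10(est) - math.log10(true_fc),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "sample",
            "reference",
            "true_fold_change",
            "estimated_fold_change",
            "relative_error",
            "log10_error",
        ],
    )
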