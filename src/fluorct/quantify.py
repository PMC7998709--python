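"""Comparative-Ct quantification on threshold-consolidated data.

Double normalisation, in the field's standard notation:

    ΔCt   = Ct(target) − Ct(control)            within one sample
    ΔΔCt  = ΔCt(sample 1) − ΔCt(sample 2)       between samples
    fold change (sample 1 / sample 2) = E^(−ΔΔCt)

with E the per-cycle amplification efficiency (2 by default).  When the
four underlying measurements were read at different fluorescence
thresholds, the raw-Ct route acquires a fluorescence coefficient,

    (N0_tar,S1/N0_ctrl,S1) / (N0_tar,S2/N0_ctrl,S2)
        = (Ft_tar,S1/Ft_ctrl,S1)·(Ft_ctrl,S2/Ft_tar,S2)·E^(−ΔΔCt),

which is algebraically identical to consolidating all records to common
per-gene thresholds first and applying plain E^(−ΔΔCt).  Both routes are
implemented; mixing thresholds *without* the coefficient is rejected.

Undetected wells are categorical: a sample whose target never amplified is
"not expressed" (reported separately, never as ratio 0), and one whose
control never amplified cannot be normalised at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .consolidate import AUTO, ConsolidatedTable
from .io import CtRecord

__all__ = [
    "DeltaCtEntry",
    "DeltaCtTable",
    "FoldChangeRow",
    "FoldChangeReport",
    "EmptyReportError",
    "delta_ct",
    "delta_delta_ct",
    "fold_change_consolidated",
    "fold_change_fluorescent",
    "delta_ct_table",
    "fold_change_report",
]


class EmptyReportError(ValueError):
    """No sample expressed the target gene; there is nothing to report."""


# ---------------------------------------------------------------------------
# scalar operations (None propagates as "missing")


def delta_ct(ct_target: float | None, ct_control: float | None) -> float | None:
    """Ct(target) − Ct(control); missing if either well was undetected."""
    if ct_target is None or ct_control is None:
        return None
    return ct_target - ct_control


def delta_delta_ct(dct_s1: float | None, dct_s2: float | None) -> float | None:
    """ΔCt(sample 1) − ΔCt(sample 2); antisymmetric; missing propagates."""
    if dct_s1 is None or dct_s2 is None:
        return None
    return dct_s1 - dct_s2


def fold_change_consolidated(
    dct_s1: float | None, dct_s2: float | None, efficiency: float = 2.0
) -> float | None:
    """Expression(sample 1) / Expression(sample 2) = E^(ΔCt_s2 − ΔCt_s1).

    Inputs must come from one consolidated table (common per-gene
    thresholds); a value above 1 means sample 1 expresses more.
    """
    ddct = delta_delta_ct(dct_s1, dct_s2)
    if ddct is None:
        return None
    return math.exp(-ddct * math.log(efficiency))


def fold_change_fluorescent(
    target_s1: CtRecord,
    control_s1: CtRecord,
    target_s2: CtRecord,
    control_s2: CtRecord,
    efficiency: float = 2.0,
) -> float | None:
    """Fold change from four raw records whose thresholds may all differ.

    The fluorescence coefficient
    (Ft_tar,S1/Ft_ctrl,S1)·(Ft_ctrl,S2/Ft_tar,S2) multiplies the usual
    E^(−ΔΔCt) computed on the raw, unconsolidated Ct values.  Equals the
    consolidate-then-compare route exactly.
    """
    four = (target_s1, control_s1, target_s2, control_s2)
    if any(not r.detected for r in four):
        return None
    ddct = (target_s1.ct - control_s1.ct) - (target_s2.ct - control_s2.ct)
    log_ratio = (
        math.log(target_s1.ft)
        - math.log(control_s1.ft)
        + math.log(control_s2.ft)
        - math.log(target_s2.ft)
        - ddct * math.log(efficiency)
    )
    return math.exp(log_ratio)


# ---------------------------------------------------------------------------
# tables


@dataclass(frozen=True)
class DeltaCtEntry:
    sample_id: str
    gene_id: str
    delta_ct: float | None
    ct_control: float | None
    expressed: bool  # target gene amplified
    normalizable: bool  # control gene amplified


@dataclass(frozen=True)
class DeltaCtTable:
    """Per-sample ΔCt values for each target gene against one control gene."""

    control_gene: str
    efficiency: float
    entries: tuple[DeltaCtEntry, ...]

    @property
    def target_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.gene_id)
        return list(seen)

    def for_gene(self, gene_id: str) -> list[DeltaCtEntry]:
        return [e for e in self.entries if e.gene_id == gene_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.sample_id, e.gene_id, e.delta_ct, e.ct_control, e.expressed, e.normalizable)
                for e in self.entries
            ],
            columns=["sample", "gene", "delta_ct", "ct_control", "expressed", "normalizable"],
        )


def _check_single_threshold_per_gene(records: Sequence[CtRecord]) -> None:
    per_gene: dict[str, set[float]] = {}
    for r in records:
        if r.detected:
            per_gene.setdefault(r.gene_id, set()).add(r.ft)
    mixed = [g for g, fts in per_gene.items() if len(fts) > 1]
    if mixed:
        raise ValueError(
            f"genes {mixed} mix fluorescence thresholds; consolidate the table "
            "first (or use fold_change_fluorescent, which carries the "
            "fluorescence coefficient)"
        )


def delta_ct_table(
    table: ConsolidatedTable | Iterable[CtRecord],
    control_gene: str | None = None,
    efficiency: float | None = None,
) -> DeltaCtTable:
    """Intra-sample normalisation of a consolidated table.

    ``control_gene`` defaults to the single gene whose records carry
    role="control".  Records must share one threshold per gene — raw
    mixed-threshold tables are rejected.
    """
    if isinstance(table, ConsolidatedTable):
        records = list(table.records)
        if efficiency is None:
            efficiency = table.efficiency
    else:
        records = list(table)
    if efficiency is None:
        efficiency = 2.0
    _check_single_threshold_per_gene(records)

    if control_gene is None:
        control_genes = {r.gene_id for r in records if r.role == "control"}
        if len(control_genes) != 1:
            raise ValueError(
                "control_gene not given and the records do not designate "
                f"exactly one control gene (found {sorted(control_genes)})"
            )
        control_gene = control_genes.pop()

    control_ct: dict[str, float | None] = {}
    for r in records:
        if r.gene_id == control_gene:
            control_ct[r.sample_id] = r.ct
    if not control_ct:
        raise ValueError(f"control gene {control_gene!r} absent from the table")

    entries: list[DeltaCtEntry] = []
    for r in records:
        if r.gene_id == control_gene:
            continue
        # a sample with no control record at all (e.g. the well was excluded
        # upstream) is treated like an undetected control: not normalizable
        cc = control_ct.get(r.sample_id)
        entries.append(
            DeltaCtEntry(
                sample_id=r.sample_id,
                gene_id=r.gene_id,
                delta_ct=delta_ct(r.ct, cc),
                ct_control=cc,
                expressed=r.detected,
                normalizable=cc is not None,
            )
        )
    return DeltaCtTable(control_gene, float(efficiency), tuple(entries))


@dataclass(frozen=True)
class FoldChangeRow:
    sample_id: str
    fold_change_ratio: float
    log10_fold_change: float


@dataclass(frozen=True)
class FoldChangeReport:
    """Per-sample expression relative to one reference sample for one gene."""

    reference_sample_id: str
    gene_id: str
    rows: tuple[FoldChangeRow, ...]
    non_expressed: tuple[str, ...] = field(default_factory=tuple)
    non_normalizable: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        for row in self.rows:
            if not row.fold_change_ratio > 0:
                raise ValueError("fold-change ratios must be positive")
            if abs(row.log10_fold_change - math.log10(row.fold_change_ratio)) > 1e-12:
                raise ValueError(
                    f"log10 column inconsistent for {row.sample_id!r}"
                )
            if row.sample_id == self.reference_sample_id and (
                row.fold_change_ratio != 1.0 or row.log10_fold_change != 0.0
            ):
                raise ValueError("reference sample must have ratio 1 and log 0")

    def ratio(self, sample_id: str) -> float:
        for row in self.rows:
            if row.sample_id == sample_id:
                return row.fold_change_ratio
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.fold_change_ratio, r.log10_fold_change) for r in self.rows],
            columns=["sample", "fold_change_ratio", "log10_fold_change"],
        )


def fold_change_report(
    table: DeltaCtTable,
    gene: str | None = None,
    reference: str = AUTO,
    efficiency: float | None = None,
) -> FoldChangeReport:
    """Fold change of every expressed sample versus one reference sample.

    With ``reference=AUTO`` the highest-expressing sample (smallest ΔCt,
    ties broken lexicographically by sample id) is chosen — the choice is
    arbitrary in the sense that all pairwise ratios are invariant to it.
    Samples whose target never amplified are listed as non-expressed;
    samples whose control never amplified as non-normalizable.
    """
    if efficiency is None:
        efficiency = table.efficiency
    if gene is None:
        genes = table.target_genes
        if len(genes) != 1:
            raise ValueError(
                f"table holds {len(genes)} target genes; pass gene= explicitly"
            )
        gene = genes[0]

    entries = table.for_gene(gene)
    if not entries:
        raise ValueError(f"gene {gene!r} absent from the ΔCt table")
    expressed = [e for e in entries if e.delta_ct is not None]
    if not expressed:
        raise EmptyReportError(f"no sample expressed {gene!r}")
    non_expressed = tuple(
        e.sample_id for e in entries if e.normalizable and not e.expressed
    )
    non_normalizable = tuple(e.sample_id for e in entries if not e.normalizable)

    if reference == AUTO:
        ref = min(expressed, key=lambda e: (e.delta_ct, e.sample_id))
    else:
        matches = [e for e in expressed if e.sample_id == reference]
        if not matches:
            raise ValueError(
                f"reference sample {reference!r} is not an expressed sample of {gene!r}"
            )
        ref = matches[0]

    rows = []
    for e in expressed:
        if e.sample_id == ref.sample_id:
            rows.append(FoldChangeRow(e.sample_id, 1.0, 0.0))
            continue
        ratio = fold_change_consolidated(e.delta_ct, ref.delta_ct, efficiency)
        rows.append(FoldChangeRow(e.sample_id, ratio, math.log10(ratio)))

    return FoldChangeReport(
        reference_sample_id=ref.sample_id,
        gene_id=gene,
        rows=tuple(rows),
        non_expressed=non_expressed,
        non_normalizable=non_normalizable,
    )
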