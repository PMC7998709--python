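"""Threshold consolidation: re-express (Ct, Ft) pairs at one common threshold.

A well read at threshold Ft with cycle threshold Ct lies on the exponential
trajectory k·N0·E^c.  Asking where the same trajectory would cross a
different threshold Ft_new gives, from Ft·E^{-Ct} = Ft_new·E^{-Ct_new},

    Ct_new = Ct + log_E(Ft_new / Ft)

so measurements collected at arbitrary per-well thresholds can be collapsed
onto a single threshold per gene — after which ordinary comparative-Ct
arithmetic applies.  The common threshold's value is arbitrary (pairwise Ct
differences within a gene are invariant to it); what matters is that it is
singular per gene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import CtRecord

__all__ = [
    "AUTO",
    "ConsolidationSpec",
    "ConsolidatedTable",
    "ConsolidationWarning",
    "consolidate_record",
    "consolidate_table",
    "geometric_mean",
]

#: sentinel requesting the per-gene geometric-mean threshold
AUTO = "auto"


class ConsolidationWarning(UserWarning):
    pass


def geometric_mean(values: Sequence[float]) -> float:
    if not values:
        raise ValueError("geometric mean of an empty sequence")
    return math.exp(sum(math.log(v) for v in values) / len(values))


@dataclass(frozen=True)
class ConsolidationSpec:
    """How to consolidate: amplification efficiency and per-gene targets.

    ``thresholds`` maps gene ids to an explicit common threshold (RFU) or
    :data:`AUTO`; genes not listed default to AUTO, which resolves to the
    geometric mean of that gene's observed thresholds.
    """

    efficiency: float = 2.0
    thresholds: Mapping[str, float | str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.efficiency > 1:
            raise ValueError(f"efficiency must be > 1, got {self.efficiency}")
        for gene, ft in self.thresholds.items():
            if ft == AUTO:
                continue
            if not (isinstance(ft, (int, float)) and math.isfinite(ft) and ft > 0):
                raise ValueError(f"threshold for {gene!r} must be > 0, got {ft!r}")


@dataclass(frozen=True)
class ConsolidatedTable:
    """CtRecords sharing one fluorescence threshold per gene.

    ``thresholds`` records the resolved common threshold per gene and
    ``provenance`` the original (ct, ft) of every detected record, so the
    transformation is auditable and reversible.
    """

    records: tuple[CtRecord, ...]
    thresholds: Mapping[str, float]
    efficiency: float
    provenance: Mapping[tuple[str, str], tuple[float, float]]

    def __post_init__(self):
        per_gene: dict[str, set[float]] = {}
        for r in self.records:
            if r.detected:
                per_gene.setdefault(r.gene_id, set()).add(r.ft)
        for gene, fts in per_gene.items():
            if len(fts) != 1:
                raise ValueError(
                    f"gene {gene!r} carries {len(fts)} distinct thresholds "
                    "after consolidation"
                )

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def consolidate_record(
    record: CtRecord, ft_new: float, efficiency: float = 2.0
) -> CtRecord:
    """Re-express one record at threshold ``ft_new``.

    Undetected records pass through unchanged: a well that never amplified
    is a category, not a number, and is never extrapolated to a Ct.
    """
    if not (isinstance(ft_new, (int, float)) and math.isfinite(ft_new) and ft_new > 0):
        raise ValueError(f"ft_new must be a finite positive number, got {ft_new!r}")
    if not efficiency > 1:
        raise ValueError(f"efficiency must be > 1, got {efficiency}")
    if not record.detected:
        return record
    ct_new = record.ct + math.log(ft_new / record.ft) / math.log(efficiency)
    return record.with_threshold(ct_new, float(ft_new))


def consolidate_table(
    records: Iterable[CtRecord], spec: ConsolidationSpec | None = None
) -> ConsolidatedTable:
    """Consolidate every detected record onto its gene's common threshold.

    AUTO thresholds resolve to the geometric mean of the gene's observed
    thresholds (the least-worst-case choice in log distance; any value
    would do).  A gene named in the spec but absent from the data warns
    rather than errors.
    """
    spec = spec or ConsolidationSpec()
    records = list(records)

    observed: dict[str, list[float]] = {}
    for r in records:
        observed.setdefault(r.gene_id, [])
        if r.detected:
            observed[r.gene_id].append(r.ft)

    for gene in spec.thresholds:
        if gene not in observed:
            warnings.warn(
                f"threshold given for gene {gene!r} not present in the data",
                ConsolidationWarning,
                stacklevel=2,
            )

    resolved: dict[str, float] = {}
    for gene, fts in observed.items():
        target = spec.thresholds.get(gene, AUTO)
        if target == AUTO:
            if not fts:  # gene never detected anywhere; nothing to consolidate
                continue
            target = geometric_mean(fts)
        resolved[gene] = float(target)

    out: list[CtRecord] = []
    provenance: dict[tuple[str, str], tuple[float, float]] = {}
    for r in records:
        if r.detected:
            provenance[(r.sample_id, r.gene_id)] = (r.ct, r.ft)
            out.append(consolidate_record(r, resolved[r.gene_id], spec.efficiency))
        else:
            out.append(r)
    return ConsolidatedTable(
        records=tuple(out),
        thresholds=resolved,
        efficiency=spec.efficiency,
        provenance=provenance,
    )
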