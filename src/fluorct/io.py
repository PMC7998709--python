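"""Plain-text interchange tables for the qPCR pipeline.

Three artefacts move between stages:

* ``ct_table.csv`` — one row per (sample, gene) well, carrying the cycle
  threshold and the fluorescence threshold it was read at
  (header ``sample,gene,role,ct,ft``).  A well whose fluorescence never
  crossed its threshold carries the literal ``Undetermined`` (any
  capitalisation) or an empty ct cell, and no ft.
* ``curves.csv`` — long-format per-cycle fluorescence export in the style
  of a real-time instrument (header ``sample,gene,cycle,fluorescence``).
* ``fold_change.csv`` — the final relative-expression report
  (header ``sample,fold_change_ratio,log10_fold_change``).

All files are UTF-8 CSV with a decimal point and no thousands separators;
LF and CRLF line endings are both accepted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "CurveSet",
    "FormatError",
    "RowParseError",
    "IntegrityError",
    "read_ct_table",
    "write_ct_table",
    "read_curves",
    "write_curves",
    "write_fold_change_report",
]

ROLES = ("target", "control")

#: literal token used by instrument exports for a well that never crossed
#: its fluorescence threshold
UNDETERMINED_TOKEN = "Undetermined"


class FormatError(ValueError):
    """The file does not have the expected table layout (e.g. missing column)."""


class RowParseError(ValueError):
    """A cell in one row could not be parsed; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class IntegrityError(ValueError):
    """The table violates a structural invariant (duplicates, cycle gaps...)."""


@dataclass(frozen=True)
class CtRecord:
    """One (sample, gene) qPCR measurement.

    ``ct`` is the (possibly fractional) cycle at which the well's
    fluorescence crossed ``ft``, the fluorescence threshold in relative
    fluorescence units.  A well that never reached its threshold is
    *undetected*: both ``ct`` and ``ft`` are ``None``.

    ``ct`` may be nonpositive on a consolidated record: re-expressing a
    measurement at a much lower threshold places the virtual crossing
    before cycle 1.  Instrument exports themselves always have ct > 0,
    which :func:`read_ct_table` enforces.
    """

    sample_id: str
    gene_id: str
    role: str = "target"
    ct: float | None = None
    ft: float | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if (self.ct is None) != (self.ft is None):
            raise ValueError(
                "ct and ft must both be present (detected) or both absent "
                f"(undetected); got ct={self.ct!r}, ft={self.ft!r}"
            )
        if self.ct is not None:
            if not math.isfinite(self.ct):
                raise ValueError(f"ct must be finite, got {self.ct!r}")
            if not (math.isfinite(self.ft) and self.ft > 0):
                raise ValueError(f"ft must be finite and > 0, got {self.ft!r}")

    @classmethod
    def undetected(cls, sample_id: str, gene_id: str, role: str = "target") -> "CtRecord":
        return cls(sample_id, gene_id, role, None, None)

    @property
    def detected(self) -> bool:
        return self.ct is not None

    def with_threshold(self, ct: float, ft: float) -> "CtRecord":
        return replace(self, ct=ct, ft=ft)


@dataclass
class CurveSet:
    """Raw per-cycle fluorescence for a collection of wells.

    ``fluorescence`` maps (sample_id, gene_id) to the readings for cycles
    1..C in order.  Values may be negative before baseline correction.
    """

    fluorescence: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fluorescence)

    def wells(self) -> list[tuple[str, str]]:
        return list(self.fluorescence)

    def __iter__(self):
        return iter(self.fluorescence.items())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sample, gene), values in self.fluorescence.items():
            for cycle, f in enumerate(values, start=1):
                rows.append((sample, gene, cycle, float(f)))
        return pd.DataFrame(rows, columns=["sample", "gene", "cycle", "fluorescence"])


# ---------------------------------------------------------------------------
# parsing helpers


def _require_columns(df: pd.DataFrame, names: Sequence[str], path) -> dict[str, str]:
    """Map lowercase canonical names to the actual column labels."""
    actual = {str(c).strip().lower(): c for c in df.columns}
    for name in names:
        if name not in actual:
            raise FormatError(f"{path}: missing required column {name!r}")
    return {name: actual[name] for name in names}


def _parse_number(cell: str, row: int, column: str) -> float:
    text = cell.strip()
    # locale strictness: decimal point only, no grouping of any kind
    if not text or any(c in text for c in ",_ '"):
        raise RowParseError(row, f"cannot parse {column}={cell!r} as a number")
    try:
        value = float(text)
    except ValueError:
        raise RowParseError(row, f"cannot parse {column}={cell!r} as a number") from None
    if not math.isfinite(value):
        raise RowParseError(row, f"{column}={cell!r} is not finite")
    return value


def read_ct_table(path: str | PathLike) -> list[CtRecord]:
    """Read a Ct table (``sample,gene,role,ct,ft``) into :class:`CtRecord` s.

    The ct cell may be the literal ``Undetermined`` (any capitalisation) or
    empty, either of which yields an undetected record with no ft.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    cols = _require_columns(df, ("sample", "gene", "role", "ct", "ft"), path)

    records: list[CtRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        values = dict(zip(df.columns, row))
        sample = str(values[cols["sample"]]).strip()
        gene = str(values[cols["gene"]]).strip()
        role = str(values[cols["role"]]).strip().lower()
        ct_cell = str(values[cols["ct"]]).strip()
        ft_cell = str(values[cols["ft"]]).strip()

        if role not in ROLES:
            raise RowParseError(i, f"role must be one of {ROLES}, got {role!r}")

        key = (sample, gene)
        if key in seen:
            raise IntegrityError(f"duplicate (sample, gene) pair {key!r}")
        seen.add(key)

        if not ct_cell or ct_cell.lower() == UNDETERMINED_TOKEN.lower():
            if ft_cell:
                raise RowParseError(
                    i, f"ft={ft_cell!r} given for an undetermined ct; expected empty"
                )
            records.append(CtRecord.undetected(sample, gene, role))
            continue

        ct = _parse_number(ct_cell, i, "ct")
        ft = _parse_number(ft_cell, i, "ft")
        if ct <= 0:
            raise RowParseError(i, f"ct must be > 0 in an exported table, got {ct}")
        if ft <= 0:
            raise RowParseError(i, f"ft must be > 0, got {ft}")
        records.append(CtRecord(sample, gene, role, ct, ft))
    return records


def write_ct_table(records: Iterable[CtRecord], path: str | PathLike) -> None:
    """Write records as ``sample,gene,role,ct,ft``; undetected → ``Undetermined``."""
    lines = ["sample,gene,role,ct,ft"]
    for r in records:
        if r.detected:
            lines.append(f"{r.sample_id},{r.gene_id},{r.role},{r.ct!r},{r.ft!r}")
        else:
            lines.append(f"{r.sample_id},{r.gene_id},{r.role},{UNDETERMINED_TOKEN},")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_curves(path: str | PathLike) -> CurveSet:
    """Read a long-format curve export into a cycle-sorted :class:`CurveSet`.

    Per well, cycles must form a contiguous ascending sequence starting at 1
    (after sorting); a gap or duplicate raises :class:`IntegrityError`
    naming the well.
    """
    df = pd.read_csv(path)
    cols = _require_columns(df, ("sample", "gene", "cycle", "fluorescence"), path)
    df = df.rename(columns={v: k for k, v in cols.items()})

    curves: dict[tuple[str, str], np.ndarray] = {}
    for (sample, gene), grp in df.groupby(["sample", "gene"], sort=False):
        grp = grp.sort_values("cycle")
        cycles = grp["cycle"].to_numpy()
        well = (str(sample), str(gene))
        if not np.array_equal(cycles, np.arange(1, len(cycles) + 1)):
            raise IntegrityError(
                f"well {well}: cycles must be contiguous 1..{len(cycles)} "
                "(gap or duplicate detected)"
            )
        values = grp["fluorescence"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise IntegrityError(f"well {well}: non-finite fluorescence value")
        curves[well] = values
    return CurveSet(curves)


def write_curves(curve_set: CurveSet, path: str | PathLike) -> None:
    curve_set.to_frame().to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# fold-change report


def format_ratio(ratio: float) -> str:
    """Format a fold-change ratio the way the report prints it.

    Three significant figures; scientific notation below 0.01 (so a ratio of
    7.06e-6 prints as ``7.06E-06`` while 0.087 stays ``0.087``); integers are
    padded to two decimals (1 → ``1.00``).
    """
    if ratio < 0.01:
        return f"{ratio:.2E}"
    s = f"{ratio:.3g}"
    if "." not in s and "e" not in s and "E" not in s:
        s += ".00"
    return s


def format_log(value: float) -> str:
    return f"{value:.2f}"


def write_fold_change_report(report, path: str | PathLike) -> None:
    """Write a fold-change report as ``sample,fold_change_ratio,log10_fold_change``.

    Expressed samples come first; samples in which the target gene never
    amplified follow with ``NA`` in both numeric columns (non-expression is
    a category, not a zero).
    """
    if not report.rows:
        raise ValueError("cannot write an empty fold-change report")
    lines = ["sample,fold_change_ratio,log10_fold_change"]
    for row in report.rows:
        lines.append(
            f"{row.sample_id},{format_ratio(row.fold_change_ratio)},"
            f"{format_log(row.log10_fold_change)}"
        )
    for sample in report.non_expressed:
        lines.append(f"{sample},NA,NA")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
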