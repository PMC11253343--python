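"""Unit helpers, report configuration, session accumulation and export.

Successive calculations accumulate in a :class:`Session` (append-only) and
export together as a single spreadsheet workbook: a ``summary`` sheet with
one row per calculation and a long-format ``calc_N`` sheet per calculation
(entity, quantity, value, unit).  A plain-text CSV export and a JSON echo
of each result are offered alongside for pipeline use.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable, Sequence

from openpyxl import Workbook, load_workbook

from .equilibrium_solver import (
    MixtureSpec,
    SpeciationResult,
    convert_unit,
)

__all__ = [
    "IonSpecies",
    "ReportConfig",
    "SessionRecord",
    "Session",
    "convert_unit",
    "ionic_equivalence",
    "append_result",
    "export_session",
    "export_session_csv",
    "result_to_json",
]


@dataclass(frozen=True)
class IonSpecies:
    """One dissolved ion: concentration in mM and its (signed) charge."""

    concentration: float
    charge: int


def ionic_equivalence(ions: Sequence[IonSpecies]) -> float:
    """Ionic equivalence Ie = 0.5 * sum(C_i * |z_i|) in mM.

    The charge-weighted sum used by this calculator lineage in place of the
    standard ionic strength (which would weight by z_i^2).
    """
    if not ions:
        raise ValueError("ionic_equivalence needs at least one ion species")
    total = 0.0
    for ion in ions:
        if ion.concentration < 0:
            raise ValueError(f"negative ion concentration {ion.concentration}")
        total += ion.concentration * abs(ion.charge)
    return 0.5 * total


@dataclass(frozen=True)
class ReportConfig:
    """Which parameters appear in the report ("show in report" selection)."""

    include_conditions: bool = True
    include_kapp: bool = False
    include_alpha: bool = False
    include_bound: bool = True
    include_px: bool = True
    metals: tuple[str, ...] | None = None  # None = all
    ligands: tuple[str, ...] | None = None

    def __post_init__(self):
        if not any(
            (
                self.include_conditions,
                self.include_kapp,
                self.include_alpha,
                self.include_bound,
                self.include_px,
            )
        ):
            raise ValueError("report must select at least one output")


@dataclass(frozen=True)
class SessionRecord:
    mixture: MixtureSpec
    result: SpeciationResult
    config: ReportConfig
    source: str
    timestamp: str = ""


@dataclass(frozen=True)
class Session:
    """Append-only ordered list of calculations."""

    records: tuple[SessionRecord, ...] = ()

    def __len__(self) -> int:
        return len(self.records)


def append_result(session: Session, record: SessionRecord) -> Session:
    """Return a session one record longer; the input session is untouched."""
    if not record.timestamp:
        record = SessionRecord(
            record.mixture,
            record.result,
            record.config,
            record.source,
            datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )
    return Session(session.records + (record,))


# ---------------------------------------------------------------------------
# export


def _metal_rows(rec: SessionRecord) -> Iterable[tuple[str, str, float, str]]:
    cfg = rec.config
    res = rec.result
    metals = cfg.metals if cfg.metals is not None else tuple(res.metals)
    ligands = cfg.ligands if cfg.ligands is not None else tuple(res.ligands)
    if cfg.include_conditions:
        c = res.conditions
        yield ("conditions", "temperature", c.temperature, "degC")
        yield ("conditions", "ph", c.ph, "pH")
        yield ("conditions", "ionic_equivalence", c.ionic_equivalence, "mM")
    for mid in metals:
        m = res.metals[mid]
        yield (mid, "free", m.free, "M")
        yield (mid, "total", m.total, "M")
        if cfg.include_px and m.px is not None:
            yield (mid, "pX", m.px, "-log10(M)")
        if cfg.include_bound:
            for lid, conc in m.bound.items():
                if lid in ligands:
                    yield (mid, f"bound_{lid}", conc, "M")
    for lid in ligands:
        lig = res.ligands[lid]
        yield (lid, "total_effective", lig.total_effective, "M")
        yield (lid, "free_unbound", lig.free_unbound, "M")


def _summary_row(idx: int, rec: SessionRecord) -> list:
    c = rec.result.conditions
    heads = []
    for mid, m in rec.result.metals.items():
        px = f"{m.px:.10g}" if m.px is not None else "n/a"
        heads.append(f"{mid}: free={m.free:.10g} M, pX={px}")
    return [
        idx,
        rec.source,
        c.temperature,
        c.ph,
        c.ionic_equivalence,
        "; ".join(heads),
        rec.timestamp,
    ]


_SUMMARY_HEADER = [
    "calc",
    "source",
    "temperature_c",
    "ph",
    "ionic_equivalence_mm",
    "headline",
    "timestamp",
]
_CALC_HEADER = ["entity", "quantity", "value", "unit"]


#: Default display precision for exports, significant decimal digits.
#: Below the solver tolerance, above lab needs, and exactly representable
#: by the spreadsheet writer so re-reading reproduces every value.
EXPORT_DIGITS = 10


def _displayed(value: float, digits: int) -> float:
    """Round to ``digits`` significant decimals with exact float round trip."""
    return float(f"{value:.{digits}g}")


def export_session(session: Session, path, digits: int = EXPORT_DIGITS) -> None:
    """Write the whole session as one XLSX workbook.

    One ``calc_N`` worksheet per calculation (long format: entity,
    quantity, value, unit; only quantities selected in that record's
    :class:`ReportConfig`) plus a ``summary`` sheet with one row per
    calculation.  Numeric cells are numbers rounded to ``digits``
    significant decimals; re-reading the workbook reproduces every
    exported value exactly.
    """
    if len(session) == 0:
        raise ValueError("cannot export an empty session")
    wb = Workbook()
    ws = wb.active
    ws.title = "summary"
    ws.append(_SUMMARY_HEADER)
    for idx, rec in enumerate(session.records, start=1):
        ws.append(_summary_row(idx, rec))
    for idx, rec in enumerate(session.records, start=1):
        sheet = wb.create_sheet(f"calc_{idx}")
        sheet.append(_CALC_HEADER)
        for entity, quantity, value, unit in _metal_rows(rec):
            sheet.append([entity, quantity, _displayed(value, digits), unit])
    wb.save(path)


def export_session_csv(session: Session, path, digits: int = EXPORT_DIGITS) -> None:
    """CSV alternative to the workbook: all calculations in one long table
    with a leading ``calc`` index column.  UTF-8, comma-delimited, same
    display precision as the workbook."""
    if len(session) == 0:
        raise ValueError("cannot export an empty session")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["calc"] + _CALC_HEADER)
        for idx, rec in enumerate(session.records, start=1):
            for entity, quantity, value, unit in _metal_rows(rec):
                writer.writerow([idx, entity, quantity, f"{value:.{digits}g}", unit])


def read_workbook_rows(path, sheet: str) -> list[list]:
    """Read back one worksheet as a list of rows (values only)."""
    wb = load_workbook(path, read_only=True)
    ws = wb[sheet]
    return [list(r) for r in ws.iter_rows(values_only=True)]


def result_to_json(result: SpeciationResult) -> str:
    """JSON echo of a result for programmatic consumption."""
    doc = {
        "conditions": {
            "temperature_c": result.conditions.temperature,
            "ph": result.conditions.ph,
            "ionic_equivalence_mm": result.conditions.ionic_equivalence,
        },
        "metals": {
            mid: {
                "free_m": m.free,
                "total_m": m.total,
                "px": m.px,
                "bound_m": dict(m.bound),
            }
            for mid, m in result.metals.items()
        },
        "ligands": {
            lid: {
                "total_effective_m": lig.total_effective,
                "free_unbound_m": lig.free_unbound,
            }
            for lid, lig in result.ligands.items()
        },
        "convergence": {
            "iterations": result.iterations,
            "residual": result.residual,
        },
        "source": result.source,
    }
    return json.dumps(doc, indent=2)
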