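"""Stability-constant datasets and their JSON interchange format.

A :class:`ConstantSet` is a named library of chelator (ligand) and metal
records carrying *absolute* association constants quoted at a reference
temperature and ionic equivalence.  Four built-in sources ship as packaged
JSON data files; user-defined sets use the same interchange format and can
be validated, serialized and round-tripped losslessly.

Conventions (recorded in the schema so custom sets are self-describing):

* all ``log_k`` are log10 *association* constants on a molar basis;
* protonation constants are *stepwise*: step 1 is the first proton onto the
  fully deprotonated ligand (its pK equals the ligand's highest pKa);
* a complex with ``protons = n`` forms from free metal plus the ligand form
  already carrying ``n`` protons (``protons = 1`` means M + HL = MHL);
* ``delta_h`` is the enthalpy of the association reaction in kJ/mol,
  exothermic negative; absent means "do not temperature-correct".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

import jsonschema

__all__ = [
    "ProtonationStep",
    "ComplexSpecies",
    "LigandRecord",
    "MetalRecord",
    "ConstantSet",
    "BUILTIN_SOURCES",
    "load_builtin",
    "parse_constant_set",
    "serialize_constant_set",
    "validate_constant_set",
    "load_schema",
]

#: Shipped source labels mapped to their packaged data files.
BUILTIN_SOURCES: Mapping[str, str] = {
    "NIST": "nist.json",
    "Chelator": "chelator.json",
    "SPECS": "specs.json",
    "Calcium": "calcium.json",
}

_SCHEMA_FILE = "constant_set.schema.json"


@dataclass(frozen=True)
class ProtonationStep:
    """One stepwise proton-association equilibrium of a ligand."""

    step_index: int
    log_k: float
    delta_h: float | None = None
    extra: Mapping[str, Any] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class ComplexSpecies:
    """A 1:1 metal-ligand complex, optionally protonated (protons >= 1)."""

    metal_id: str
    protons: int
    log_k: float
    delta_h: float | None = None
    extra: Mapping[str, Any] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class LigandRecord:
    """A chelator: charge of the fully deprotonated form, protonation ladder
    and the metal complexes it forms, all at one reference condition."""

    ligand_id: str
    charge: int
    protonation: tuple[ProtonationStep, ...]
    complexes: tuple[ComplexSpecies, ...]
    ref_temperature: float
    ref_ionic_equivalence: float
    extra: Mapping[str, Any] = field(default_factory=dict, compare=False)

    def max_protonation(self) -> int:
        return max((s.step_index for s in self.protonation), default=0)

    def complexes_for(self, metal_id: str) -> tuple[ComplexSpecies, ...]:
        return tuple(c for c in self.complexes if c.metal_id == metal_id)


@dataclass(frozen=True)
class MetalRecord:
    metal_id: str
    charge: int
    extra: Mapping[str, Any] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class ConstantSet:
    source_name: str
    metals: tuple[MetalRecord, ...]
    ligands: tuple[LigandRecord, ...]
    citation: str = ""
    extra: Mapping[str, Any] = field(default_factory=dict, compare=False)

    def metal(self, metal_id: str) -> MetalRecord:
        for m in self.metals:
            if m.metal_id == metal_id:
                return m
        raise KeyError(f"unknown metal id {metal_id!r}")

    def ligand(self, ligand_id: str) -> LigandRecord:
        for lig in self.ligands:
            if lig.ligand_id == ligand_id:
                return lig
        raise KeyError(f"unknown ligand id {ligand_id!r}")


# ---------------------------------------------------------------------------
# loading


def load_schema() -> dict:
    """Return the JSON schema for the constant-set interchange format."""
    text = resources.files("freemetal.data").joinpath(_SCHEMA_FILE).read_text()
    return json.loads(text)


def load_builtin(source_name: str = "NIST") -> ConstantSet:
    """Load one of the four shipped constant sources.

    Parameters
    ----------
    source_name
        One of ``NIST`` (default), ``Chelator``, ``SPECS``, ``Calcium``.
    """
    if source_name not in BUILTIN_SOURCES:
        valid = ", ".join(sorted(BUILTIN_SOURCES))
        raise ValueError(
            f"unknown constant source {source_name!r}; valid sources: {valid}"
        )
    text = (
        resources.files("freemetal.data")
        .joinpath(BUILTIN_SOURCES[source_name])
        .read_text()
    )
    return parse_constant_set(text)


# ---------------------------------------------------------------------------
# JSON interchange

_KNOWN_TOP = {"source", "citation", "metals", "ligands"}
_KNOWN_METAL = {"id", "charge"}
_KNOWN_LIGAND = {
    "id",
    "charge",
    "ref_temperature_c",
    "ref_ionic_equivalence_mm",
    "protonation",
    "complexes",
}
_KNOWN_STEP = {"step", "log_k", "delta_h_kj_mol"}
_KNOWN_COMPLEX = {"metal", "protons", "log_k", "delta_h_kj_mol"}


def _extras(obj: Mapping[str, Any], known: set[str]) -> dict[str, Any]:
    return {k: v for k, v in obj.items() if k not in known}


def parse_constant_set(document: str) -> ConstantSet:
    """Parse a JSON constant-set document.

    Unknown keys are preserved on the records (and re-emitted by
    :func:`serialize_constant_set`) but ignored by all computation.

    Raises
    ------
    ValueError
        On malformed JSON (with position) or schema violations (with the
        offending field path).
    """
    try:
        data = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"malformed JSON at line {exc.lineno} column {exc.colno}: {exc.msg}"
        ) from exc
    try:
        jsonschema.validate(data, load_schema())
    except jsonschema.ValidationError as exc:
        path = "/".join(str(p) for p in exc.absolute_path) or "<document root>"
        raise ValueError(f"constant-set schema violation at {path}: {exc.message}") from exc

    metals = tuple(
        MetalRecord(m["id"], int(m["charge"]), extra=_extras(m, _KNOWN_METAL))
        for m in data["metals"]
    )
    ligands = []
    for lig in data["ligands"]:
        steps = tuple(
            ProtonationStep(
                int(s["step"]),
                float(s["log_k"]),
                None if s.get("delta_h_kj_mol") is None else float(s["delta_h_kj_mol"]),
                extra=_extras(s, _KNOWN_STEP),
            )
            for s in lig.get("protonation", [])
        )
        cplx = tuple(
            ComplexSpecies(
                c["metal"],
                int(c["protons"]),
                float(c["log_k"]),
                None if c.get("delta_h_kj_mol") is None else float(c["delta_h_kj_mol"]),
                extra=_extras(c, _KNOWN_COMPLEX),
            )
            for c in lig.get("complexes", [])
        )
        ligands.append(
            LigandRecord(
                lig["id"],
                int(lig["charge"]),
                steps,
                cplx,
                float(lig["ref_temperature_c"]),
                float(lig["ref_ionic_equivalence_mm"]),
                extra=_extras(lig, _KNOWN_LIGAND),
            )
        )
    return ConstantSet(
        source_name=data.get("source", "custom"),
        metals=metals,
        ligands=tuple(ligands),
        citation=data.get("citation", ""),
        extra=_extras(data, _KNOWN_TOP),
    )


def serialize_constant_set(cset: ConstantSet) -> str:
    """Serialize to the JSON interchange format.

    Key order is fixed (known keys first, preserved extras after), so
    serialization is deterministic: serializing twice yields byte-identical
    text, and ``parse(serialize(s)) == s``.
    """

    def step_obj(s: ProtonationStep) -> dict:
        d: dict[str, Any] = {"step": s.step_index, "log_k": s.log_k,
                             "delta_h_kj_mol": s.delta_h}
        d.update(s.extra)
        return d

    def cplx_obj(c: ComplexSpecies) -> dict:
        d: dict[str, Any] = {"metal": c.metal_id, "protons": c.protons,
                             "log_k": c.log_k, "delta_h_kj_mol": c.delta_h}
        d.update(c.extra)
        return d

    def lig_obj(lig: LigandRecord) -> dict:
        d: dict[str, Any] = {
            "id": lig.ligand_id,
            "charge": lig.charge,
            "ref_temperature_c": lig.ref_temperature,
            "ref_ionic_equivalence_mm": lig.ref_ionic_equivalence,
            "protonation": [step_obj(s) for s in lig.protonation],
            "complexes": [cplx_obj(c) for c in lig.complexes],
        }
        d.update(lig.extra)
        return d

    def metal_obj(m: MetalRecord) -> dict:
        d: dict[str, Any] = {"id": m.metal_id, "charge": m.charge}
        d.update(m.extra)
        return d

    doc: dict[str, Any] = {
        "source": cset.source_name,
        "citation": cset.citation,
        "metals": [metal_obj(m) for m in cset.metals],
        "ligands": [lig_obj(lig) for lig in cset.ligands],
    }
    doc.update(cset.extra)
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# validation


def validate_constant_set(cset: ConstantSet) -> list[str]:
    """Check every type invariant; return a list of human-readable issues.

    An empty list means the set is valid.  Issues are data, not exceptions,
    so a UI can show all of them at once.
    """
    import math

    issues: list[str] = []

    if not cset.ligands:
        issues.append("constant set: ligand list is empty")

    seen_m: set[str] = set()
    for m in cset.metals:
        if m.metal_id in seen_m:
            issues.append(f"metal {m.metal_id!r}: duplicate metal_id")
        seen_m.add(m.metal_id)
        if m.charge not in (1, 2, 3):
            issues.append(
                f"metal {m.metal_id!r}: charge must be 1, 2 or 3, got {m.charge}"
            )

    seen_l: set[str] = set()
    for lig in cset.ligands:
        name = f"ligand {lig.ligand_id!r}"
        if lig.ligand_id in seen_l:
            issues.append(f"{name}: duplicate ligand_id")
        seen_l.add(lig.ligand_id)
        if not lig.protonation and not lig.complexes:
            issues.append(f"{name}: needs at least one protonation step or complex")
        if not math.isfinite(lig.ref_temperature):
            issues.append(f"{name}: ref_temperature not finite")
        if not math.isfinite(lig.ref_ionic_equivalence):
            issues.append(f"{name}: ref_ionic_equivalence not finite")

        steps = sorted(s.step_index for s in lig.protonation)
        if steps != list(range(1, len(steps) + 1)):
            issues.append(
                f"{name}: protonation step indices {steps} are not "
                "consecutive starting at 1"
            )
        if len(steps) > 4:
            issues.append(f"{name}: more than 4 protonation steps")
        for s in lig.protonation:
            if not math.isfinite(s.log_k):
                issues.append(f"{name} step {s.step_index}: log_k not finite")

        nmax = lig.max_protonation()
        for c in lig.complexes:
            cname = f"{name} complex with {c.metal_id!r}"
            if c.metal_id not in seen_m and c.metal_id not in {
                m.metal_id for m in cset.metals
            }:
                issues.append(f"{cname}: metal_id does not resolve to a metal record")
            if c.protons < 0:
                issues.append(f"{cname}: protons must be >= 0, got {c.protons}")
            elif c.protons > nmax:
                issues.append(
                    f"{cname}: protons = {c.protons} exceeds the ligand's "
                    f"{nmax} protonation steps"
                )
            if not math.isfinite(c.log_k):
                issues.append(f"{cname}: log_k not finite")

    return issues
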