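"""Apparent (conditional) stability constants at user conditions.

Absolute association constants are quoted at a reference temperature and
ionic equivalence.  Three corrections convert them to the single effective
("apparent") constant between free metal and *all* non-metal-bound ligand
forms at the working conditions:

1. van't Hoff temperature correction using the association enthalpy;
2. an extended Debye-Hueckel activity correction in the ionic equivalence
   Ie = 0.5 * sum(C_i * |z_i|), the convention of this calculator lineage;
3. proton competition at the working pH via the alpha fraction (the share
   of unbound ligand that is fully deprotonated and metal-avid).

pH is interpreted as -log10 of the free proton *concentration*; no
electrode/activity conversion is applied (users may pre-correct).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

from .constants_store import ConstantSet, LigandRecord, MetalRecord

__all__ = [
    "GAS_CONSTANT_J_PER_MOL_K",
    "CELSIUS_OFFSET_K",
    "BufferConditions",
    "ApparentConstantTable",
    "validate_conditions",
    "vant_hoff_adjust",
    "debye_huckel_slope",
    "debye_huckel_term",
    "ionic_strength_adjust",
    "proton_competition",
    "corrected_protonation",
    "apparent_constant",
    "build_table",
]

#: Molar gas constant, J/(mol K).
GAS_CONSTANT_J_PER_MOL_K = 8.31446
#: 0 degrees Celsius in kelvin.
CELSIUS_OFFSET_K = 273.15

TEMPERATURE_RANGE_C = (0.0, 40.0)
PH_RANGE = (0.0, 14.0)
IONIC_EQUIVALENCE_RANGE_MM = (0.0, 500.0)


@dataclass(frozen=True)
class BufferConditions:
    """Experimental context for all corrections.

    temperature in degrees C, ph in pH units, ionic_equivalence in mM.
    """

    temperature: float
    ph: float
    ionic_equivalence: float


def validate_conditions(conditions: BufferConditions) -> list[str]:
    """Check conditions against the supported ranges.

    Returns an empty list when valid; otherwise one message per violated
    field naming the value and the accepted closed range (temperature
    0-40 C, pH 0-14, ionic equivalence 0-500 mM, the latter exclusive at 0).
    """
    violations: list[str] = []
    lo, hi = TEMPERATURE_RANGE_C
    if not (lo <= conditions.temperature <= hi):
        violations.append(
            f"temperature {conditions.temperature} degC outside the accepted "
            f"range {lo}-{hi} degC"
        )
    lo, hi = PH_RANGE
    if not (lo <= conditions.ph <= hi):
        violations.append(f"ph {conditions.ph} outside the accepted range {lo}-{hi}")
    lo, hi = IONIC_EQUIVALENCE_RANGE_MM
    if not (lo < conditions.ionic_equivalence <= hi):
        violations.append(
            f"ionic_equivalence {conditions.ionic_equivalence} mM outside the "
            f"accepted range ({lo}, {hi}] mM"
        )
    return violations


def _require_valid(conditions: BufferConditions) -> None:
    violations = validate_conditions(conditions)
    if violations:
        raise ValueError("; ".join(violations))


# ---------------------------------------------------------------------------
# temperature correction


def vant_hoff_adjust(
    log_k: float,
    delta_h: float | None,
    t_ref: float,
    t_target: float,
) -> float:
    """van't Hoff correction of a log10 constant between two temperatures.

    log K(T) = log K(T_ref) - (dH / (ln 10 * R)) * (1/T - 1/T_ref), with
    temperatures in kelvin and ``delta_h`` in kJ/mol (association reaction,
    exothermic negative).  A missing enthalpy leaves the constant unchanged.
    """
    if delta_h is None:
        return log_k
    if not all(math.isfinite(x) for x in (log_k, delta_h, t_ref, t_target)):
        raise ValueError("van't Hoff inputs must be finite")
    tk_ref = t_ref + CELSIUS_OFFSET_K
    tk_target = t_target + CELSIUS_OFFSET_K
    dh_j = delta_h * 1000.0
    return log_k - dh_j / (math.log(10.0) * GAS_CONSTANT_J_PER_MOL_K) * (
        1.0 / tk_target - 1.0 / tk_ref
    )


# ---------------------------------------------------------------------------
# ionic-strength correction


def debye_huckel_slope(temperature: float) -> float:
    """Debye-Hueckel A coefficient for water at ``temperature`` (degrees C).

    A = 1.824829e6 * (eps(T) * T_K)**-1.5 with the Malmberg-Maryott
    polynomial for the static dielectric constant of water:
    eps(t) = 87.740 - 0.40008 t + 9.398e-4 t^2 - 1.410e-6 t^3 (t in degC).
    Approximately 0.507 at 20 C and 0.511 at 25 C.
    """
    t = temperature
    eps = 87.740 - 0.40008 * t + 9.398e-4 * t * t - 1.410e-6 * t**3
    tk = t + CELSIUS_OFFSET_K
    return 1.824829e6 * (eps * tk) ** -1.5


def debye_huckel_term(ionic_equivalence: float, temperature: float) -> float:
    """Activity term f(Ie, T) = A(T) * (sqrt(I)/(1+sqrt(I)) - 0.25*I).

    ``ionic_equivalence`` is in mM and is used directly as the "I" of the
    extended Debye-Hueckel expression (in molar), per the ionic-equivalence
    convention of this calculator family.  The term multiplies z^2 in
    log gamma_i = -z_i^2 * f.  f -> 0 at infinite dilution and is
    increasing on the supported 0-500 mM range.
    """
    if ionic_equivalence < 0:
        raise ValueError(f"ionic equivalence must be >= 0, got {ionic_equivalence}")
    i_molar = ionic_equivalence / 1000.0
    root = math.sqrt(i_molar)
    return debye_huckel_slope(temperature) * (root / (1.0 + root) - 0.25 * i_molar)


def ionic_strength_adjust(
    log_k: float,
    delta_z_sq: int,
    ie_ref: float,
    ie_target: float,
    temperature: float,
) -> float:
    """Move a log10 association constant between two ionic equivalences.

    With log gamma_i = -z_i^2 * f(Ie, T) and
    ``delta_z_sq = sum z^2(reactants) - z^2(product)``:

        log K(Ie) = log K(Ie_ref) - delta_z_sq * (f(Ie) - f(Ie_ref))

    For a charge-neutralizing association (delta_z_sq > 0, e.g. Ca2+ +
    EGTA4- where delta_z_sq = 4 + 16 - 4 = 16) the apparent constant
    decreases as ionic strength rises, the experimentally observed
    screening direction.
    """
    f_ref = debye_huckel_term(ie_ref, temperature)
    f_target = debye_huckel_term(ie_target, temperature)
    return log_k - delta_z_sq * (f_target - f_ref)


# ---------------------------------------------------------------------------
# proton competition


def proton_competition(log_ks: Sequence[float], ph: float) -> float:
    """Fraction alpha of unbound ligand in the fully deprotonated form.

    ``log_ks`` are the condition-corrected *stepwise* proton association
    constants, ordered step 1..n (step 1 = first proton onto the bare
    ligand).  alpha = 1 / (1 + sum_i (prod_{j<=i} K_Hj) * [H+]^i) with
    [H+] = 10**-ph.  An empty ladder gives alpha = 1; alpha is
    nondecreasing in pH.
    """
    h = 10.0 ** (-ph)
    total = 1.0
    cum_log_beta = 0.0
    for i, log_k in enumerate(log_ks, start=1):
        cum_log_beta += log_k
        total += 10.0 ** (cum_log_beta - i * ph)
    return 1.0 / total


def corrected_protonation(
    ligand: LigandRecord, conditions: BufferConditions
) -> list[float]:
    """Stepwise protonation log K of ``ligand`` at the working conditions.

    Each step gets the same two corrections as metal constants (temperature
    first, then ionic strength at the target temperature).  For step j,
    H+ (z=1) + ligand form of charge (z_L + j - 1) gives charge (z_L + j):
    delta_z_sq = 1 + (z_L+j-1)^2 - (z_L+j)^2.
    """
    out = []
    for step in sorted(ligand.protonation, key=lambda s: s.step_index):
        z_before = ligand.charge + step.step_index - 1
        z_after = z_before + 1
        dz2 = 1 + z_before * z_before - z_after * z_after
        log_k = vant_hoff_adjust(
            step.log_k, step.delta_h, ligand.ref_temperature, conditions.temperature
        )
        log_k = ionic_strength_adjust(
            log_k,
            dz2,
            ligand.ref_ionic_equivalence,
            conditions.ionic_equivalence,
            conditions.temperature,
        )
        out.append(log_k)
    return out


# ---------------------------------------------------------------------------
# apparent constant


def _corrected_complex_log_k(
    ligand: LigandRecord,
    metal: MetalRecord,
    protons: int,
    log_k: float,
    delta_h: float | None,
    conditions: BufferConditions,
) -> float:
    # M(z_M) + H_nL(z_L + n) -> MH_nL(z_M + z_L + n)
    z_l_form = ligand.charge + protons
    z_prod = metal.charge + z_l_form
    dz2 = metal.charge**2 + z_l_form**2 - z_prod**2
    adjusted = vant_hoff_adjust(
        log_k, delta_h, ligand.ref_temperature, conditions.temperature
    )
    return ionic_strength_adjust(
        adjusted,
        dz2,
        ligand.ref_ionic_equivalence,
        conditions.ionic_equivalence,
        conditions.temperature,
    )


def apparent_constant(
    ligand: LigandRecord, metal: MetalRecord, conditions: BufferConditions
) -> float:
    """Apparent association constant K_app (M^-1) for one metal-ligand pair.

    Every stored constant is van't Hoff-adjusted then ionic-strength-
    adjusted.  Complexes with n protons are promoted to cumulative
    formation constants from the bare ligand, beta_MHnL = K_MHnL *
    prod_{j<=n} K_Hj, and combined with proton competition:

        K_app = alpha * sum_n beta_MHnL * [H+]^n

    K_app relates free metal to the *total* unbound ligand pool (all
    protonation states), which is what the mass-balance solver consumes.
    """
    _require_valid(conditions)
    complexes = ligand.complexes_for(metal.metal_id)
    if not complexes:
        raise ValueError(
            f"no complex recorded between metal {metal.metal_id!r} and "
            f"ligand {ligand.ligand_id!r}"
        )
    log_kh = corrected_protonation(ligand, conditions)
    alpha = proton_competition(log_kh, conditions.ph)

    total = 0.0
    for c in complexes:
        log_k = _corrected_complex_log_k(
            ligand, metal, c.protons, c.log_k, c.delta_h, conditions
        )
        # cumulative beta from bare ligand: add the proton-loading steps
        log_beta = log_k + sum(log_kh[: c.protons])
        total += 10.0 ** (log_beta - c.protons * conditions.ph)
    return alpha * total


# ---------------------------------------------------------------------------
# table


@dataclass(frozen=True)
class ApparentConstantTable:
    """Apparent constants for a selection, valid only at one condition set.

    ``entries`` maps (metal_id, ligand_id) to K_app in M^-1; ``alpha`` maps
    ligand_id to its deprotonated fraction.  Immutable once built.
    """

    conditions: BufferConditions
    entries: Mapping[tuple[str, str], float]
    alpha: Mapping[str, float]

    def k_app(self, metal_id: str, ligand_id: str) -> float:
        return self.entries.get((metal_id, ligand_id), 0.0)


def build_table(
    cset: ConstantSet,
    metal_ids: Iterable[str],
    ligand_ids: Iterable[str],
    conditions: BufferConditions,
) -> ApparentConstantTable:
    """Build an :class:`ApparentConstantTable` for a metal/ligand selection.

    One entry per selected pair that has at least one recorded complex;
    pairs with no constants are simply absent (K_app treated as 0).
    """
    violations = validate_conditions(conditions)
    if violations:
        raise ValueError("; ".join(violations))
    metals = [cset.metal(mid) for mid in metal_ids]
    ligands = [cset.ligand(lid) for lid in ligand_ids]

    entries: dict[tuple[str, str], float] = {}
    alpha: dict[str, float] = {}
    for lig in ligands:
        alpha[lig.ligand_id] = proton_competition(
            corrected_protonation(lig, conditions), conditions.ph
        )
        for m in metals:
            if lig.complexes_for(m.metal_id):
                entries[(m.metal_id, lig.ligand_id)] = apparent_constant(
                    lig, m, conditions
                )
    return ApparentConstantTable(
        conditions=conditions,
        entries=MappingProxyType(entries),
        alpha=MappingProxyType(alpha),
    )
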