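"""Coupled mass-balance solver for metal-chelator mixtures.

The speciation model: with apparent constants K(m, j) between free metal m
and the total unbound pool of ligand j, equilibrium requires

    M_total,m = M_free,m * (1 + sum_j K(m,j) * L_free,j)
    L_total,j = L_free,j * (1 + sum_m K(m,j) * M_free,m)

where L_free is the metal-free ligand in *all* protonation states and the
bound amount of each pair is K(m,j) * M_free,m * L_free,j.  Two modes are
supported: total metal known (solve for free), and free metal known (hold
the free value fixed, solve the rest, then report the required total).

Arithmetic runs either in native floats or, for users who want to rule out
rounding artifacts, in arbitrary-precision decimals via the standard
``decimal`` module at a configurable number of significant digits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import Decimal, localcontext
from typing import Literal, Mapping

from .apparent_constants import ApparentConstantTable, BufferConditions

__all__ = [
    "ChelatorEntry",
    "MetalEntry",
    "MixtureSpec",
    "MetalResult",
    "LigandResult",
    "SpeciationResult",
    "ArithmeticContext",
    "ConvergenceError",
    "UNIT_EXPONENT",
    "convert_unit",
    "apply_purity",
    "closed_form_1_1",
    "p_transform",
    "with_precision",
    "solve_free_from_total",
    "solve_total_from_free",
]

#: Power-of-ten exponent to molar for the accepted units ("uM" is accepted
#: as an ASCII spelling of μM).
UNIT_EXPONENT: Mapping[str, int] = {
    "M": 0,
    "mM": -3,
    "uM": -6,
    "μM": -6,
    "nM": -9,
}

RELATIVE_TOLERANCE = 1e-12
MAX_ITERATIONS = 10_000


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


def convert_unit(value: float, unit: str) -> float:
    """Convert a concentration in M, mM, uM (μM) or nM to molar.

    The power-of-ten scaling is exact in the decimal sense: the result is
    the correctly rounded float of ``value`` shifted by the unit's decimal
    exponent (so 250 nM gives exactly 2.5e-7, with no binary drift).
    """
    if unit not in UNIT_EXPONENT:
        raise ValueError(f"unknown unit {unit!r}; accepted units: M, mM, uM, nM")
    exp = UNIT_EXPONENT[unit]
    if exp == 0:
        return float(value)
    return float(Decimal(repr(float(value))).scaleb(exp))


@dataclass(frozen=True)
class ChelatorEntry:
    """One chelator in the recipe: nominal concentration and assay purity."""

    ligand_id: str
    concentration: float
    unit: str = "M"
    purity: float = 100.0


@dataclass(frozen=True)
class MetalEntry:
    """One metal in the recipe; ``mode`` says whether the given
    concentration is the total or the desired free value."""

    metal_id: str
    concentration: float
    unit: str = "M"
    mode: Literal["total_known", "free_known"] = "total_known"


@dataclass(frozen=True)
class MixtureSpec:
    chelators: tuple[ChelatorEntry, ...]
    metals: tuple[MetalEntry, ...]
    conditions: BufferConditions

    def __post_init__(self):
        ids = [c.ligand_id for c in self.chelators] + [m.metal_id for m in self.metals]
        if len(set(ids)) != len(ids):
            raise ValueError("mixture ids must be unique")
        if not self.chelators and not self.metals:
            raise ValueError("mixture needs at least one metal or chelator")


def apply_purity(entry: ChelatorEntry) -> float:
    """Effective total chelator concentration in molar: nominal x purity."""
    if not (0.0 < entry.purity <= 100.0):
        raise ValueError(
            f"purity must be in (0, 100], got {entry.purity} for {entry.ligand_id!r}"
        )
    if entry.concentration < 0:
        raise ValueError(f"negative concentration for {entry.ligand_id!r}")
    return convert_unit(entry.concentration, entry.unit) * entry.purity / 100.0


@dataclass(frozen=True)
class MetalResult:
    free: float
    total: float
    bound: Mapping[str, float]
    px: float | None


@dataclass(frozen=True)
class LigandResult:
    total_effective: float
    free_unbound: float


@dataclass(frozen=True)
class SpeciationResult:
    metals: Mapping[str, MetalResult]
    ligands: Mapping[str, LigandResult]
    iterations: int
    residual: float
    conditions: BufferConditions
    source: str = ""


@dataclass(frozen=True)
class ArithmeticContext:
    """Solver arithmetic: native floats or fixed-precision decimals.

    ``precision`` is significant decimal digits (>= 15, the native float
    capability); it is honoured only in ``arbitrary-precision`` mode.  The
    default arbitrary-precision setting is 50 digits.
    """

    precision: int = 50
    mode: Literal["native-float", "arbitrary-precision"] = "native-float"

    def __post_init__(self):
        if self.precision < 15:
            raise ValueError(
                f"precision must be >= 15 significant digits, got {self.precision}"
            )


def with_precision(ctx: ArithmeticContext, digits: int) -> ArithmeticContext:
    """Return a context carrying >= ``digits`` significant decimal digits."""
    if digits < 15:
        raise ValueError(f"precision must be >= 15 significant digits, got {digits}")
    return replace(ctx, precision=digits)


def p_transform(free: float) -> float | None:
    """pX = -log10(free concentration); None when free <= 0 (undefined)."""
    free = float(free)
    if free <= 0.0:
        return None
    return -math.log10(free)


# ---------------------------------------------------------------------------
# closed form for the 1 metal x 1 ligand system (also a test oracle)


def _sqrt(x):
    return x.sqrt() if isinstance(x, Decimal) else math.sqrt(x)


def closed_form_1_1(m_total, l_total, k_app):
    """Free metal for a single metal-ligand pair, by the stable quadratic.

    Solves K*Mf^2 + (1 + K*(L_T - M_T))*Mf - M_T = 0 for the positive root,
    using the form that avoids cancellation for either sign of the linear
    coefficient.  Accepts floats or Decimals (the arithmetic follows the
    input type).
    """
    zero = m_total * 0
    one = zero + 1
    if k_app == zero or l_total == zero:
        return m_total
    b = one + k_app * (l_total - m_total)
    disc = b * b + 4 * k_app * m_total
    root = _sqrt(disc)
    if b >= zero:
        return (2 * m_total) / (b + root)
    return (root - b) / (2 * k_app)


# ---------------------------------------------------------------------------
# the iterative solver


def _as_number(x: float, decimal_mode: bool):
    return Decimal(repr(float(x))) if decimal_mode else float(x)


def _rel_change(new, old, zero):
    scale = abs(new) if abs(new) > abs(old) else abs(old)
    if scale == zero:
        return zero
    return abs(new - old) / scale


def _iterate(m_tot, l_tot, kmat, fixed_free, tol, zero, one):
    """Damped alternating fixed-point on the coupled mass balances.

    ``fixed_free`` maps metal index -> prescribed free value (free-known
    mode); those metals are never updated.  Updates alternate L then M;
    a 0.5 damping factor engages per-variable once its update direction
    oscillates.  Convergence requires both the max relative change and the
    max relative mass-balance residual below ``tol``.
    """
    n_m, n_l = len(m_tot), len(l_tot)
    m_free = [fixed_free.get(i, m_tot[i]) for i in range(n_m)]
    l_free = list(l_tot)
    half = one / 2
    last_dir_m = [zero] * n_m
    last_dir_l = [zero] * n_l
    damp_m = [False] * n_m
    damp_l = [False] * n_l

    max_change = zero
    for it in range(1, MAX_ITERATIONS + 1):
        max_change = zero
        for j in range(n_l):
            denom = one
            for i in range(n_m):
                denom += kmat[i][j] * m_free[i]
            raw = l_tot[j] / denom
            step = raw - l_free[j]
            if step * last_dir_l[j] < zero:
                damp_l[j] = True
            last_dir_l[j] = step
            new = l_free[j] + step * half if damp_l[j] else raw
            ch = _rel_change(new, l_free[j], zero)
            if ch > max_change:
                max_change = ch
            l_free[j] = new
        for i in range(n_m):
            if i in fixed_free:
                continue
            denom = one
            for j in range(n_l):
                denom += kmat[i][j] * l_free[j]
            raw = m_tot[i] / denom
            step = raw - m_free[i]
            if step * last_dir_m[i] < zero:
                damp_m[i] = True
            last_dir_m[i] = step
            new = m_free[i] + step * half if damp_m[i] else raw
            ch = _rel_change(new, m_free[i], zero)
            if ch > max_change:
                max_change = ch
            m_free[i] = new

        if max_change < tol:
            resid = _max_residual(m_tot, l_tot, kmat, fixed_free, m_free, l_free, zero, one)
            if resid < tol:
                return m_free, l_free, it, resid

    # fixed point stalled: for a single unknown metal, bisect its residual
    unknown = [i for i in range(n_m) if i not in fixed_free]
    if len(unknown) == 1:
        i = unknown[0]
        m_free, l_free = _bisect_single(i, m_tot, l_tot, kmat, fixed_free, tol, zero, one)
        resid = _max_residual(m_tot, l_tot, kmat, fixed_free, m_free, l_free, zero, one)
        if resid < tol * 10:
            return m_free, l_free, MAX_ITERATIONS, resid
    resid = _max_residual(m_tot, l_tot, kmat, fixed_free, m_free, l_free, zero, one)
    raise ConvergenceError(
        f"speciation solver did not converge in {MAX_ITERATIONS} iterations "
        f"(last relative residual {float(resid):.3e})",
        float(resid),
        MAX_ITERATIONS,
    )


def _max_residual(m_tot, l_tot, kmat, fixed_free, m_free, l_free, zero, one):
    worst = zero
    for i in range(len(m_tot)):
        if i in fixed_free:
            continue
        denom = one
        for j in range(len(l_tot)):
            denom += kmat[i][j] * l_free[j]
        if m_tot[i] > zero:
            r = abs(m_free[i] * denom - m_tot[i]) / m_tot[i]
            if r > worst:
                worst = r
    for j in range(len(l_tot)):
        denom = one
        for i in range(len(m_tot)):
            denom += kmat[i][j] * m_free[i]
        if l_tot[j] > zero:
            r = abs(l_free[j] * denom - l_tot[j]) / l_tot[j]
            if r > worst:
                worst = r
    return worst


def _bisect_single(i, m_tot, l_tot, kmat, fixed_free, tol, zero, one):
    """Bracketing fallback on the single-metal residual; ligands eliminated
    in closed form at each trial value."""

    def ligands_at(m_i):
        frees = []
        for j in range(len(l_tot)):
            denom = one
            for k in range(len(m_tot)):
                mk = fixed_free.get(k, m_i if k == i else zero)
                denom += kmat[k][j] * mk
            frees.append(l_tot[j] / denom)
        return frees

    def residual(m_i):
        lf = ligands_at(m_i)
        denom = one
        for j in range(len(l_tot)):
            denom += kmat[i][j] * lf[j]
        return m_i * denom - m_tot[i]

    lo, hi = zero, m_tot[i]
    for _ in range(300):
        mid = (lo + hi) / 2
        if residual(mid) > zero:
            hi = mid
        else:
            lo = mid
        if hi > zero and (hi - lo) / hi < tol / 10:
            break
    mid = (lo + hi) / 2
    out = list(m_tot)
    for k, v in fixed_free.items():
        out[k] = v
    out[i] = mid
    return out, ligands_at(mid)


def _solve(
    mixture: MixtureSpec,
    table: ApparentConstantTable,
    ctx: ArithmeticContext,
    fixed_modes: bool,
) -> SpeciationResult:
    if table.conditions != mixture.conditions:
        raise ValueError(
            "apparent-constant table was built for different conditions than "
            "the mixture"
        )
    decimal_mode = ctx.mode == "arbitrary-precision"

    metal_ids = [m.metal_id for m in mixture.metals]
    ligand_ids = [c.ligand_id for c in mixture.chelators]

    def run():
        zero = _as_number(0.0, decimal_mode)
        one = _as_number(1.0, decimal_mode)
        tol = (
            Decimal(f"1e-{-round(math.log10(RELATIVE_TOLERANCE))}")
            if decimal_mode
            else RELATIVE_TOLERANCE
        )
        l_tot = [_as_number(apply_purity(c), decimal_mode) for c in mixture.chelators]
        kmat = [
            [
                _as_number(table.k_app(mid, lid), decimal_mode)
                for lid in ligand_ids
            ]
            for mid in metal_ids
        ]
        fixed: dict[int, object] = {}
        m_tot_in = []
        for i, m in enumerate(mixture.metals):
            conc = _as_number(convert_unit(m.concentration, m.unit), decimal_mode)
            if m.concentration < 0:
                raise ValueError(f"negative concentration for {m.metal_id!r}")
            if m.mode == "free_known":
                if not fixed_modes:
                    raise ValueError(
                        f"metal {m.metal_id!r} is in free_known mode; use "
                        "solve_total_from_free"
                    )
                fixed[i] = conc
                m_tot_in.append(conc)  # placeholder; total computed afterwards
            else:
                m_tot_in.append(conc)
        if fixed_modes and not fixed:
            raise ValueError("solve_total_from_free needs >= 1 free_known metal")

        m_free, l_free, its, resid = _iterate(
            m_tot_in, l_tot, kmat, fixed, tol, zero, one
        )

        metals_out: dict[str, MetalResult] = {}
        for i, mid in enumerate(metal_ids):
            bound = {
                lid: float(kmat[i][j] * m_free[i] * l_free[j])
                for j, lid in enumerate(ligand_ids)
            }
            if i in fixed:
                denom = one
                for j in range(len(ligand_ids)):
                    denom += kmat[i][j] * l_free[j]
                total = float(m_free[i] * denom)
            else:
                total = float(m_tot_in[i])
            free = float(m_free[i])
            metals_out[mid] = MetalResult(
                free=free, total=total, bound=bound, px=p_transform(free)
            )
        ligands_out = {
            lid: LigandResult(
                total_effective=float(l_tot[j]), free_unbound=float(l_free[j])
            )
            for j, lid in enumerate(ligand_ids)
        }
        return SpeciationResult(
            metals=metals_out,
            ligands=ligands_out,
            iterations=its,
            residual=float(resid),
            conditions=mixture.conditions,
        )

    if decimal_mode:
        with localcontext() as dctx:
            dctx.prec = ctx.precision
            return run()
    return run()


def solve_free_from_total(
    mixture: MixtureSpec,
    table: ApparentConstantTable,
    ctx: ArithmeticContext | None = None,
) -> SpeciationResult:
    """Solve for free metal concentrations given total concentrations.

    All metals must be in ``total_known`` mode and the table must have been
    built at the mixture's conditions.  Raises :class:`ConvergenceError`
    (carrying the last residual) if the iteration fails.
    """
    ctx = ctx or ArithmeticContext()
    for m in mixture.metals:
        if m.mode != "total_known":
            raise ValueError(
                f"metal {m.metal_id!r} is in {m.mode} mode; "
                "solve_free_from_total requires total_known for all metals"
            )
    return _solve(mixture, table, ctx, fixed_modes=False)


def solve_total_from_free(
    mixture: MixtureSpec,
    table: ApparentConstantTable,
    ctx: ArithmeticContext | None = None,
) -> SpeciationResult:
    """Solve for the total metal needed to reach prescribed free values.

    Metals in ``free_known`` mode are held fixed at their given free
    concentration while the remaining system equilibrates; their required
    totals are then total = free * (1 + sum_j K_app * L_free_j).
    """
    ctx = ctx or ArithmeticContext()
    if not any(m.mode == "free_known" for m in mixture.metals):
        raise ValueError("solve_total_from_free needs >= 1 metal in free_known mode")
    return _solve(mixture, table, ctx, fixed_modes=True)
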