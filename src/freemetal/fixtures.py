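"""Synthetic constant sets, random mixtures, and an independent oracle.

Everything here exists so the rest of the package is testable without any
external data: :func:`make_synthetic_constant_set` draws validate-clean
constant sets from seeded uniform ranges, :func:`make_random_mixture`
builds recipes over them, and :func:`brute_force_speciation_oracle` solves
the same mass-balance system as the production solver by a completely
different route (nested scalar root bracketing with closed-form ligand
elimination), sharing no solver code.

Default log K ranges span weak ATP-like (1e2 M^-1) through strong
EGTA-like (1e11 M^-1) binding; protonation pK values span 1-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .apparent_constants import ApparentConstantTable, BufferConditions
from .constants_store import (
    ComplexSpecies,
    ConstantSet,
    LigandRecord,
    MetalRecord,
    ProtonationStep,
)
from .equilibrium_solver import (
    ChelatorEntry,
    MetalEntry,
    MixtureSpec,
    apply_purity,
    convert_unit,
)

__all__ = [
    "FixtureSpec",
    "make_synthetic_constant_set",
    "make_random_mixture",
    "brute_force_speciation_oracle",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic constant set; same seed, same fixture."""

    n_metals: int = 2
    n_ligands: int = 2
    log_k_range: tuple[float, float] = (2.0, 11.0)
    pk_range: tuple[float, float] = (1.0, 10.0)
    protonation_steps: tuple[int, int] = (0, 4)
    seed: int = 0


def make_synthetic_constant_set(spec: FixtureSpec) -> ConstantSet:
    """Draw a validate-clean synthetic :class:`ConstantSet`.

    Metals are divalent (``M1``..), ligands tetravalent anions (``L1``..).
    Every metal-ligand pair gets an ML complex; pairs on ligands with at
    least one protonation step also get an MHL complex with a weaker
    constant.  pK ladders are sorted descending so step 1 is the most
    basic site, matching real chelators.
    """
    rng = np.random.default_rng(spec.seed)
    metals = tuple(
        MetalRecord(f"M{i + 1}", 2) for i in range(spec.n_metals)
    )
    ligands = []
    for j in range(spec.n_ligands):
        n_steps = int(rng.integers(spec.protonation_steps[0], spec.protonation_steps[1] + 1))
        pks = np.sort(rng.uniform(*spec.pk_range, size=n_steps))[::-1]
        steps = tuple(
            ProtonationStep(k + 1, float(pk), None) for k, pk in enumerate(pks)
        )
        complexes = []
        for m in metals:
            log_k = float(rng.uniform(*spec.log_k_range))
            complexes.append(ComplexSpecies(m.metal_id, 0, log_k, None))
            if n_steps >= 1:
                complexes.append(
                    ComplexSpecies(
                        m.metal_id, 1, max(0.5, log_k - float(rng.uniform(4, 8))), None
                    )
                )
        ligands.append(
            LigandRecord(
                f"L{j + 1}",
                -4,
                steps,
                tuple(complexes),
                ref_temperature=20.0,
                ref_ionic_equivalence=100.0,
            )
        )
    return ConstantSet(
        source_name="custom",
        metals=metals,
        ligands=tuple(ligands),
        citation=f"synthetic fixture, seed {spec.seed}, numpy default_rng",
    )


def make_random_mixture(
    cset: ConstantSet,
    conditions: BufferConditions,
    seed: int,
    conc_range_mm: tuple[float, float] = (0.05, 5.0),
) -> MixtureSpec:
    """A random total-known mixture over every metal and ligand in ``cset``."""
    rng = np.random.default_rng(seed)
    chelators = tuple(
        ChelatorEntry(
            lig.ligand_id,
            float(rng.uniform(*conc_range_mm)),
            "mM",
            purity=float(rng.uniform(90.0, 100.0)),
        )
        for lig in cset.ligands
    )
    metals = tuple(
        MetalEntry(m.metal_id, float(rng.uniform(*conc_range_mm)), "mM", "total_known")
        for m in cset.metals
    )
    return MixtureSpec(chelators, metals, conditions)


# ---------------------------------------------------------------------------
# independent oracle


def brute_force_speciation_oracle(
    mixture: MixtureSpec, table: ApparentConstantTable
) -> dict[str, float]:
    """Free metal concentrations by nested scalar root bracketing.

    For trial free-metal values the unbound ligand pools follow in closed
    form, L_j = L_T,j / (1 + sum_m K(m,j) M_m); each metal's mass-balance
    residual M_m (1 + sum_j K(m,j) L_j) - M_T,m is strictly increasing in
    its own free value, so the unknowns are solved by nested bracketing on
    [0, M_T] to below 1e-14 relative.  Limited to 3 metals x 3 ligands (the
    nesting is exponential by design; this is a verification oracle, not a
    production path).
    """
    metal_ids = [m.metal_id for m in mixture.metals]
    ligand_ids = [c.ligand_id for c in mixture.chelators]
    if len(metal_ids) > 3 or len(ligand_ids) > 3:
        raise ValueError("oracle supports at most 3 metals and 3 ligands")
    for m in mixture.metals:
        if m.mode != "total_known":
            raise ValueError("oracle handles total_known metals only")

    m_tot = [convert_unit(m.concentration, m.unit) for m in mixture.metals]
    l_tot = [apply_purity(c) for c in mixture.chelators]
    kmat = [[table.k_app(mid, lid) for lid in ligand_ids] for mid in metal_ids]

    def ligand_frees(m_free: list[float]) -> list[float]:
        return [
            l_tot[j] / (1.0 + sum(kmat[i][j] * m_free[i] for i in range(len(m_tot))))
            for j in range(len(l_tot))
        ]

    def residual(i: int, m_free: list[float]) -> float:
        lf = ligand_frees(m_free)
        return (
            m_free[i] * (1.0 + sum(kmat[i][j] * lf[j] for j in range(len(l_tot))))
            - m_tot[i]
        )

    def solve_level(level: int, m_free: list[float]) -> list[float]:
        """Solve metals level..n-1 given frees of metals 0..level-1."""
        if level == len(m_tot):
            return m_free

        def outer_residual(x: float) -> float:
            trial = list(m_free)
            trial[level] = x
            inner = solve_level(level + 1, trial)
            return residual(level, inner)

        if m_tot[level] == 0.0:
            root = 0.0
        else:
            lo, hi = 0.0, m_tot[level]
            if outer_residual(hi) <= 0.0:
                root = hi  # unbound limit (no ligands / zero K)
            else:
                # xtol must not dominate: free metal can sit at 1e-12 M, so
                # the absolute tolerance is pushed far below any concentration
                root = brentq(
                    outer_residual, lo, hi, rtol=1e-15, xtol=1e-30, maxiter=600
                )
        trial = list(m_free)
        trial[level] = root
        return solve_level(level + 1, trial)

    solution = solve_level(0, list(m_tot))
    return dict(zip(metal_ids, solution))
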