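import pytest

from freemetal import (
    BufferConditions,
    ChelatorEntry,
    ComplexSpecies,
    ConstantSet,
    LigandRecord,
    MetalEntry,
    MetalRecord,
    MixtureSpec,
    ProtonationStep,
    build_table,
    load_builtin,
)

STANDARD = BufferConditions(temperature=20.0, ph=7.0, ionic_equivalence=100.0)


@pytest.fixture
def standard_conditions():
    """pH 7.0, 20 degC, Ie 100 mM — the bench-standard buffer context."""
    return STANDARD


@pytest.fixture(scope="session")
def nist():
    return load_builtin("NIST")


@pytest.fixture
def toy_ligand():
    """EGTA-like 4-step chelator with ML and MHL complexes for one metal."""
    return LigandRecord(
        "TOY",
        -4,
        (
            ProtonationStep(1, 9.4, -23.4),
            ProtonationStep(2, 8.8, -21.3),
            ProtonationStep(3, 2.7, None),
            ProtonationStep(4, 2.0, None),
        ),
        (
            ComplexSpecies("Ca", 0, 10.86, -33.1),
            ComplexSpecies("Ca", 1, 3.8, None),
        ),
        ref_temperature=20.0,
        ref_ionic_equivalence=100.0,
    )


@pytest.fixture
def toy_set(toy_ligand):
    return ConstantSet("custom", (MetalRecord("Ca", 2),), (toy_ligand,))


@pytest.fixture(scope="session")
def titration_points(nist):
    """The comparison buffer: 2 mM ATP, 1 mM EGTA, 6 mM Mg at pH 7.0,
    20 degC, Ie 100 mM, with total Ca swept across the EGTA capacity."""
    table = build_table(nist, ["Ca", "Mg"], ["EGTA", "ATP"], STANDARD)
    mixtures = []
    for k in range(20):
        ca_total_mm = 0.05 + k * 0.05  # 0.05 .. 1.0 mM
        mixtures.append(
            MixtureSpec(
                (
                    ChelatorEntry("EGTA", 1.0, "mM"),
                    ChelatorEntry("ATP", 2.0, "mM"),
                ),
                (
                    MetalEntry("Ca", ca_total_mm, "mM", "total_known"),
                    MetalEntry("Mg", 6.0, "mM", "total_known"),
                ),
                STANDARD,
            )
        )
    return table, mixtures
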