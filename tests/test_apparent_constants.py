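import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freemetal.apparent_constants import (
    BufferConditions,
    apparent_constant,
    build_table,
    corrected_protonation,
    debye_huckel_slope,
    debye_huckel_term,
    ionic_strength_adjust,
    proton_competition,
    validate_conditions,
    vant_hoff_adjust,
)
from freemetal.constants_store import (
    ComplexSpecies,
    ConstantSet,
    LigandRecord,
    MetalRecord,
)

# ---------------------------------------------------------------------------
# condition validation


@pytest.mark.parametrize(
    "temp,ph,ie,n_violations",
    [
        (20.0, 7.0, 100.0, 0),
        (0.0, 0.0, 500.0, 0),     # boundaries are inclusive
        (40.0, 14.0, 0.001, 0),
        (41.0, 7.0, 100.0, 1),
        (-0.1, 7.0, 100.0, 1),
        (20.0, 14.1, 100.0, 1),
        (20.0, 7.0, 501.0, 1),
        (20.0, 7.0, 0.0, 1),      # Ie must be strictly positive
        (45.0, -1.0, 600.0, 3),
    ],
)
def test_validate_conditions_ranges(temp, ph, ie, n_violations):
    violations = validate_conditions(BufferConditions(temp, ph, ie))
    assert len(violations) == n_violations
    for v in violations:
        # each violation names field, value and accepted range
        assert any(f in v for f in ("temperature", "ph", "ionic_equivalence"))
        assert "range" in v


# ---------------------------------------------------------------------------
# van't Hoff


def test_vant_hoff_missing_enthalpy_is_identity():
    assert vant_hoff_adjust(10.0, None, 25.0, 5.0) == 10.0


def test_vant_hoff_same_temperature_is_identity():
    assert vant_hoff_adjust(10.0, -33.6, 25.0, 25.0) == pytest.approx(10.0, abs=1e-15)


def test_vant_hoff_matches_hand_evaluation():
    # logK 10.0, dH -33.6 kJ/mol, 25 -> 20 degC; closed form evaluated
    # independently at 40 digits
    assert vant_hoff_adjust(10.0, -33.6, 25.0, 20.0) == pytest.approx(
        10.100400258853714, rel=1e-12
    )


def test_vant_hoff_exothermic_weakens_with_heating():
    cold = vant_hoff_adjust(10.0, -30.0, 20.0, 10.0)
    hot = vant_hoff_adjust(10.0, -30.0, 20.0, 35.0)
    assert cold > 10.0 > hot


def test_vant_hoff_rejects_non_finite():
    with pytest.raises(ValueError):
        vant_hoff_adjust(float("nan"), -30.0, 20.0, 25.0)


# ---------------------------------------------------------------------------
# Debye-Hueckel


def test_slope_near_room_temperature():
    # the canonical "~0.51" coefficient; hand values at 40 digits
    assert debye_huckel_slope(20.0) == pytest.approx(0.50712360817130118, rel=1e-12)
    assert 0.49 < debye_huckel_slope(0.0) < debye_huckel_slope(40.0) < 0.53


def test_dh_term_hand_value_and_dilution_limit():
    assert debye_huckel_term(100.0, 20.0) == pytest.approx(
        0.10915991522824937, rel=1e-12
    )
    assert debye_huckel_term(0.0, 20.0) == 0.0
    assert debye_huckel_term(1e-9, 20.0) == pytest.approx(0.0, abs=1e-6)


def test_dh_term_increasing_then_flat_top():
    """f rises across the working range and stays nonnegative.

    The linear -0.25*I tail makes f turn over just below 500 mM (the
    stationary point of sqrt(I)/(1+sqrt(I)) - I/4 sits near I = 0.485 M),
    so strict monotonicity holds up to ~480 mM and the remaining tail is
    flat to within a few 1e-6.
    """
    ies = np.linspace(0.5, 480.0, 400)
    vals = [debye_huckel_term(ie, 20.0) for ie in ies]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    top = [debye_huckel_term(ie, 20.0) for ie in np.linspace(480.0, 500.0, 40)]
    assert all(v >= 0 for v in vals + top)
    assert max(top) - min(top) < 5e-5


def test_dh_term_rejects_negative_ie():
    with pytest.raises(ValueError):
        debye_huckel_term(-1.0, 20.0)


def test_ionic_adjust_identities():
    assert ionic_strength_adjust(10.86, 16, 100.0, 100.0, 20.0) == 10.86
    assert ionic_strength_adjust(3.0, 0, 100.0, 400.0, 20.0) == 3.0


def test_ionic_adjust_ca_egta_hand_value():
    # Ca2+ + EGTA4-: dz2 = 4 + 16 - 4 = 16; 100 -> 150 mM at 20 degC
    assert ionic_strength_adjust(10.86, 16, 100.0, 150.0, 20.0) == pytest.approx(
        10.645617040725852, rel=1e-12
    )


def test_ionic_adjust_screens_charge_neutralization():
    # higher salt weakens a +/- association
    assert ionic_strength_adjust(10.86, 16, 100.0, 300.0, 20.0) < 10.86
    assert ionic_strength_adjust(10.86, 16, 100.0, 10.0, 20.0) > 10.86


# ---------------------------------------------------------------------------
# proton competition


def test_alpha_no_steps_is_one():
    assert proton_competition([], 7.0) == 1.0
    assert proton_competition([], 2.0) == 1.0


def test_alpha_high_ph_limit():
    assert proton_competition([9.4, 8.8, 2.7, 2.0], 14.0) == pytest.approx(
        1.0, rel=1e-4
    )


def test_alpha_hand_polynomial_value():
    # pK 9.4, 8.8, 2.7, 2.0 at pH 7.0; polynomial evaluated independently
    # at 40 digits
    assert proton_competition([9.4, 8.8, 2.7, 2.0], 7.0) == pytest.approx(
        6.2104414659110043e-5, rel=1e-12
    )


@settings(deadline=None, derandomize=True)
@given(
    ph=st.floats(0.0, 14.0),
    pks=st.lists(st.floats(1.0, 11.0), min_size=0, max_size=4),
)
def test_alpha_bounds_and_monotonicity(ph, pks):
    pks = sorted(pks, reverse=True)
    a = proton_competition(pks, ph)
    assert 0.0 < a <= 1.0
    if ph <= 13.9:
        assert proton_competition(pks, ph + 0.1) >= a


# ---------------------------------------------------------------------------
# apparent constant


def _bare_set(log_k=6.0):
    lig = LigandRecord(
        "L", -2, (), (ComplexSpecies("Ca", 0, log_k, None),), 20.0, 100.0
    )
    return ConstantSet("custom", (MetalRecord("Ca", 2),), (lig,))


def test_exact_reduction_no_protonation(standard_conditions):
    # no protonation, no MHL, reference conditions: K_app = 10**logK exactly
    cset = _bare_set(6.0)
    k = apparent_constant(cset.ligand("L"), cset.metal("Ca"), standard_conditions)
    assert k == pytest.approx(10.0**6.0, rel=1e-14)


def test_identity_at_reference_conditions(toy_set, standard_conditions):
    # dH-free constants at (T_ref, Ie_ref): corrections cancel exactly, so
    # K_app is the alpha-weighted beta sum of the stored values
    lig = toy_set.ligand("TOY")
    log_kh = corrected_protonation(lig, standard_conditions)
    assert log_kh == pytest.approx([9.4, 8.8, 2.7, 2.0], rel=1e-14)


def test_apparent_constant_composes_alpha_and_beta(toy_set, standard_conditions):
    lig, metal = toy_set.ligand("TOY"), toy_set.metal("Ca")
    alpha = proton_competition([9.4, 8.8, 2.7, 2.0], 7.0)
    beta_ml = 10.0**10.86
    beta_mhl = 10.0 ** (3.8 + 9.4)  # K_MHL * K_H1
    expected = alpha * (beta_ml + beta_mhl * 1e-7)
    k = apparent_constant(lig, metal, standard_conditions)
    assert k == pytest.approx(expected, rel=1e-12)


def test_kapp_nondecreasing_in_ph_without_mhl():
    lig = LigandRecord(
        "L",
        -4,
        (
            # pK ladder without MHL species
            *[],
        ),
        (ComplexSpecies("Ca", 0, 10.0, None),),
        20.0,
        100.0,
    )
    import dataclasses

    from freemetal.constants_store import ProtonationStep

    lig = dataclasses.replace(
        lig,
        protonation=(
            ProtonationStep(1, 9.4),
            ProtonationStep(2, 8.8),
            ProtonationStep(3, 2.7),
            ProtonationStep(4, 2.0),
        ),
    )
    metal = MetalRecord("Ca", 2)
    ks = [
        apparent_constant(lig, metal, BufferConditions(20.0, ph, 100.0))
        for ph in np.linspace(4.0, 9.0, 26)
    ]
    assert all(b >= a for a, b in zip(ks, ks[1:]))


def test_missing_pair_raises_naming_both(toy_set, standard_conditions):
    with pytest.raises(ValueError) as err:
        apparent_constant(
            toy_set.ligand("TOY"), MetalRecord("Mg", 2), standard_conditions
        )
    assert "Mg" in str(err.value) and "TOY" in str(err.value)


def test_correction_order_is_benign(toy_set):
    """Swapping temperature/ionic-strength correction order moves log K_app
    by < 1e-6 across the validated grid for |dH| <= 60 kJ/mol.

    The two corrections act on log K additively with the ionic-strength
    shift evaluated at the *target* temperature, so the swap can only
    differ through A(T); this documents the effect is negligible.
    """
    from freemetal.apparent_constants import (
        _corrected_complex_log_k,
        debye_huckel_term,
        vant_hoff_adjust,
    )

    lig = toy_set.ligand("TOY")
    metal = toy_set.metal("Ca")
    for temp in (0.0, 10.0, 25.0, 40.0):
        for ie in (10.0, 100.0, 500.0):
            cond = BufferConditions(temp, 7.0, ie)
            for c in lig.complexes:
                ours = _corrected_complex_log_k(
                    lig, metal, c.protons, c.log_k, c.delta_h, cond
                )
                # swapped order: ionic first (at target T), then van't Hoff
                z_l = lig.charge + c.protons
                dz2 = metal.charge**2 + z_l**2 - (metal.charge + z_l) ** 2
                swapped = c.log_k - dz2 * (
                    debye_huckel_term(ie, temp)
                    - debye_huckel_term(lig.ref_ionic_equivalence, temp)
                )
                swapped = vant_hoff_adjust(
                    swapped, c.delta_h, lig.ref_temperature, temp
                )
                assert abs(ours - swapped) < 1e-6


# ---------------------------------------------------------------------------
# table


def test_build_table_cardinality_and_consistency(nist, standard_conditions):
    table = build_table(nist, ["Ca", "Mg"], ["EGTA", "EDTA"], standard_conditions)
    assert len(table.entries) == 4
    for (mid, lid), k in table.entries.items():
        direct = apparent_constant(
            nist.ligand(lid), nist.metal(mid), standard_conditions
        )
        assert k == pytest.approx(direct, rel=1e-15)
    assert set(table.alpha) == {"EGTA", "EDTA"}
    for a in table.alpha.values():
        assert 0.0 < a <= 1.0


def test_build_table_deterministic(nist, standard_conditions):
    t1 = build_table(nist, ["Ca"], ["EGTA"], standard_conditions)
    t2 = build_table(nist, ["Ca"], ["EGTA"], standard_conditions)
    assert t1 == t2


def test_build_table_rejects_bad_conditions(nist):
    with pytest.raises(ValueError, match="temperature"):
        build_table(nist, ["Ca"], ["EGTA"], BufferConditions(45.0, 7.0, 100.0))


def test_build_table_rejects_unknown_ids(nist, standard_conditions):
    with pytest.raises(KeyError):
        build_table(nist, ["Fe"], ["EGTA"], standard_conditions)
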