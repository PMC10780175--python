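"""Ionization, partition coefficients and concentration conversions."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalpk.drug import (blood_to_plasma, compute_kps, load_drug,
                          membrane_affinity, neutral_fraction,
                          ng_per_ml_to_umol_per_l, plasma_to_blood,
                          umol_per_l_to_ng_per_ml, PLASMA_COMPOSITION)
from renalpk.physiology import get_physiology


def test_bundled_compound_profile(drug):
    assert drug.name == "84-B10"
    assert drug.mw == 473.15
    assert drug.pka_acid == 4.22
    assert drug.logp == 4.82
    assert drug.fu_plasma == pytest.approx(0.0061)
    assert drug.cl_hepatic == drug.cl_renal == 4.26
    assert drug.bp_ratio == 1.50


@pytest.mark.parametrize("pka,ph,expected,tol", [
    (4.22, 4.22, 0.5, 1e-12),            # pH = pKa symmetry
    (4.22, 7.4, 6.603e-4, 1e-6),         # 1 / (1 + 10^3.18)
])
def test_neutral_fraction_closed_form(pka, ph, expected, tol):
    assert neutral_fraction(pka, ph) == pytest.approx(expected, abs=tol)


def test_neutral_fraction_fully_protonated_at_low_ph():
    assert neutral_fraction(4.22, 1.0) >= 0.999


@given(st.floats(min_value=0.0, max_value=14.0),
       st.floats(min_value=0.0, max_value=14.0))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_neutral_fraction_strictly_decreasing_in_ph(ph1, ph2):
    lo, hi = sorted((ph1, ph2))
    if hi > lo:
        assert neutral_fraction(4.22, hi) < neutral_fraction(4.22, lo)


def test_kp_neutral_case_is_unity():
    """A partitioning-neutral compound in plasma-like tissue has Kp ~ 1."""
    drug = dataclasses.replace(load_drug(), logp=0.0, fu_plasma=1.0)
    phys = get_physiology("rat")
    plasma_like = dataclasses.replace(
        phys.tissues["muscle"],
        fraction_water=PLASMA_COMPOSITION["water"],
        fraction_lipid=PLASMA_COMPOSITION["lipid"],
        fraction_protein=PLASMA_COMPOSITION["protein"])
    phys = dataclasses.replace(
        phys, tissues={**phys.tissues, "muscle": plasma_like})
    kps = compute_kps(drug, phys)
    assert kps.kp["muscle"] == pytest.approx(1.0, rel=0.05)


def test_kp_lipophilicity_and_organ_ordering(drug, rat_kps):
    # lipid-rich adipose out-partitions lean muscle for this lipophilic acid
    assert rat_kps.kp["adipose"] > rat_kps.kp["muscle"]
    for organ in ("kidney", "liver", "lung"):
        assert rat_kps.kp[organ] > 1.0
    assert all(v > 0 for v in rat_kps.kp.values())


def test_kp_independent_of_body_weight(drug):
    small = compute_kps(drug, get_physiology("human", 50.0))
    large = compute_kps(drug, get_physiology("human", 100.0))
    for name, v in small.kp.items():
        assert large.kp[name] == pytest.approx(v, rel=1e-12)


def test_kp_alternate_heuristic_positive(drug, rat_phys):
    kps = compute_kps(drug, rat_phys, method="logp_fu_heuristic")
    assert all(v > 0 for v in kps.kp.values())
    with pytest.raises(ValueError):
        compute_kps(drug, rat_phys, method="nope")


def test_membrane_affinity_between_ionized_and_neutral_limits():
    p = membrane_affinity(4.82, 4.22, ph=7.4)
    assert 10 ** 3.82 < p < 10 ** 4.82


def test_blood_plasma_conversion_round_trip():
    assert plasma_to_blood(100.0, 1.50) == 150.0
    assert plasma_to_blood(0.0, 1.50) == 0.0
    assert blood_to_plasma(plasma_to_blood(37.2, 1.5), 1.5) == pytest.approx(37.2)


def test_concentration_unit_conversion_matches_molecular_weight():
    assert ng_per_ml_to_umol_per_l(473.15, 473.15) == pytest.approx(1.0)
    assert umol_per_l_to_ng_per_ml(1.0, 473.15) == pytest.approx(473.15)
    assert umol_per_l_to_ng_per_ml(
        ng_per_ml_to_umol_per_l(88.8, 473.15), 473.15) == pytest.approx(88.8)
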