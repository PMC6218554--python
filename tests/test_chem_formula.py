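"""Exact-mass chemistry: masses, adducts, enumeration, isotopes, classes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holosphere import chem_formula as cf
from holosphere.constants import ISOTOPES, MONOISOTOPIC_MASS
from holosphere.synthetic_data import random_formula, simulate_spectrum


# ---------------------------------------------------------------------------
# Formula container
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text, expected",
    [
        ("C24H32O8", {"C": 24, "H": 32, "O": 8}),
        ("C7H15NO4S", {"C": 7, "H": 15, "N": 1, "O": 4, "S": 1}),
        ("H", {"H": 1}),
    ],
)
def test_formula_parses_hill_notation(text, expected):
    f = cf.Formula.from_string(text)
    assert {el: n for el, n in f.counts} == expected
    assert str(f) == text  # round trip


def test_formula_rejects_bad_input():
    with pytest.raises(ValueError):
        cf.Formula.from_string("C2X5")
    with pytest.raises(ValueError):
        cf.Formula({"C": -1})
    with pytest.raises(ValueError):
        cf.Formula({})


def test_hill_order_puts_carbon_then_hydrogen_first():
    f = cf.Formula({"S": 1, "O": 4, "H": 15, "N": 1, "C": 7})
    assert str(f) == "C7H15NO4S"


# ---------------------------------------------------------------------------
# Monoisotopic mass
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "formula, expected",
    [
        # candidate disease-indicator compounds with published exact masses
        ("C24H32O8", 448.2097),  # 17-beta-estradiol-3-glucuronide
        ("C7H15NO4S", 209.0722),  # dihomomethionine
        ("C17H20N4O2", 312.1586),
        ("C47H88O16P2", 970.5547),
        ("C14H34N6O", 302.2794),
    ],
)
def test_monoisotopic_mass_matches_published_values(formula, expected):
    assert cf.monoisotopic_mass(formula) == pytest.approx(expected, abs=2e-4)


def test_single_hydrogen_mass_is_the_constant():
    assert cf.monoisotopic_mass("H") == MONOISOTOPIC_MASS["H"]


def test_masses_agree_with_pyteomics(rng):
    """Cross-check the internal mass table against an independent library."""
    from pyteomics import mass as ptmass

    for _ in range(20):
        f = random_formula(rng, (100, 1000))
        theirs = ptmass.calculate_mass(formula=str(f))
        assert cf.monoisotopic_mass(f) == pytest.approx(theirs, abs=1e-4)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_mass_is_additive_over_formula_union(seed):
    rng = np.random.default_rng(seed)
    f1 = random_formula(rng, (100, 500))
    f2 = random_formula(rng, (100, 500))
    assert cf.monoisotopic_mass(f1 + f2) == pytest.approx(
        cf.monoisotopic_mass(f1) + cf.monoisotopic_mass(f2), abs=1e-9
    )


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------


def test_deprotonated_ion_subtracts_one_proton():
    # neutral norspermine derivative minus a proton
    assert cf.adduct_mz("C14H34N6O", "[M-H]-") == pytest.approx(301.2721, abs=2e-4)


def test_shift_only_adduct_on_zero_mass():
    assert cf.adduct_mz(0.0, "[M+H]+") == pytest.approx(1.00728, abs=1e-5)


def test_ammoniated_dimer():
    assert cf.adduct_mz("C24H32O8", "[2M+NH4]+") == pytest.approx(914.4532, abs=5e-4)


def test_doubly_charged_adduct_halves_the_mass_scale():
    adduct = cf.Adduct.from_name("[M+H+NH4]2+")
    assert adduct.charge == 2 and adduct.multimer == 1
    m = cf.monoisotopic_mass("C47H88O16P2")
    expected = (m + 1.007276 + 18.033823) / 2
    assert cf.adduct_mz("C47H88O16P2", adduct) == pytest.approx(expected, abs=1e-4)


def test_adduct_electron_correction_sign():
    # [M-H]- keeps the electron: shift = -(H) + e = -proton
    neg = cf.Adduct.from_name("[M-H]-")
    assert neg.mass_shift == pytest.approx(-1.007276, abs=1e-6)
    pos = cf.Adduct.from_name("[M+H]+")
    assert pos.mass_shift == pytest.approx(1.007276, abs=1e-6)


# ---------------------------------------------------------------------------
# Formula enumeration
# ---------------------------------------------------------------------------


def test_enumeration_contains_published_formula():
    hits = cf.enumerate_formulas(448.2097, tol_ppm=0.5)
    assert "C24H32O8" in {str(c.formula) for c in hits}
    # every hit respects the tolerance, and ranking is by |ppm error|
    assert all(abs(c.ppm_error) <= 0.5 for c in hits)
    errors = [abs(c.ppm_error) for c in hits]
    assert errors == sorted(errors)


def test_enumeration_small_mass_glycine():
    hits = cf.enumerate_formulas(75.0320, tol_ppm=5.0)
    assert "C2H5NO2" in {str(c.formula) for c in hits}


def test_enumeration_unique_window_is_methane():
    hits = cf.enumerate_formulas(
        16.0313, tol_ppm=1.0, bounds={"C": 2, "H": 6, "N": 1, "O": 1, "P": 0, "S": 0}
    )
    assert [str(c.formula) for c in hits] == ["CH4"]


def test_enumeration_refuses_oversized_lattice():
    with pytest.raises(ValueError, match="safety limit"):
        cf.enumerate_formulas(500.0, bounds={"C": 500, "N": 500, "O": 500})


def test_empty_result_is_not_an_error():
    assert cf.enumerate_formulas(16.0313, tol_ppm=0.01,
                                 bounds={"C": 1, "H": 2, "N": 1, "O": 1}) == []


def _brute_force_enumerate(target, tol_ppm, bounds):
    """Independent oracle: plain nested loops over the full lattice."""
    out = set()
    tol = tol_ppm * 1e-6 * target
    for c in range(bounds["C"] + 1):
        for h in range(bounds["H"] + 1):
            for n in range(bounds["N"] + 1):
                for o in range(bounds["O"] + 1):
                    for s in range(bounds["S"] + 1):
                        for p in range(bounds["P"] + 1):
                            if c + h + n + o + s + p == 0:
                                continue
                            mass = (
                                c * 12.0
                                + h * MONOISOTOPIC_MASS["H"]
                                + n * MONOISOTOPIC_MASS["N"]
                                + o * MONOISOTOPIC_MASS["O"]
                                + s * MONOISOTOPIC_MASS["S"]
                                + p * MONOISOTOPIC_MASS["P"]
                            )
                            if abs(mass - target) <= tol:
                                if c - h / 2 + n / 2 + p / 2 + 1 >= 0:
                                    out.add((c, h, n, o, p, s))
    return out


def test_enumeration_agrees_with_brute_force_oracle():
    bounds = {"C": 10, "H": 20, "N": 4, "O": 6, "S": 2, "P": 1}
    rng = np.random.default_rng(7)
    targets = rng.uniform(60, 280, 25)
    for target in targets:
        expected = _brute_force_enumerate(target, 20.0, bounds)
        got = {
            tuple(c.formula[el] for el in ("C", "H", "N", "O", "P", "S"))
            for c in cf.enumerate_formulas(target, 20.0, bounds)
        }
        assert got == expected


def test_round_trip_mass_to_formula(rng):
    for _ in range(50):
        f = random_formula(rng, (100, 900))
        hits = cf.enumerate_formulas(cf.monoisotopic_mass(f), tol_ppm=0.5)
        assert str(f) in {str(c.formula) for c in hits}


def test_enumeration_on_ion_mz_scale():
    mz = cf.adduct_mz("C24H32O8", "[M-H]-")
    hits = cf.enumerate_formulas(mz, tol_ppm=0.5, adduct="[M-H]-")
    assert "C24H32O8" in {str(c.formula) for c in hits}


def test_ratio_filters_drop_implausible_formulas():
    loose = cf.enumerate_formulas(448.2097, tol_ppm=5.0)
    tight = cf.enumerate_formulas(448.2097, tol_ppm=5.0, ratio_filters=True)
    kept = {str(c.formula) for c in tight}
    assert kept < {str(c.formula) for c in loose}
    assert "C24H32O8" in kept
    for cand in tight:
        f = cand.formula
        assert 0.2 <= f["H"] / f["C"] <= 3.1


# ---------------------------------------------------------------------------
# Isotope patterns
# ---------------------------------------------------------------------------


def test_single_carbon_pattern_is_binomial():
    pattern = cf.isotope_pattern("C", min_rel_abundance=1e-4)
    assert len(pattern.peaks) == 2
    (m0, r0), (m1, r1) = pattern.peaks
    assert m0 == pytest.approx(12.0) and r0 == 1.0
    assert m1 == pytest.approx(13.00335, abs=1e-5)
    assert r1 == pytest.approx(0.0107 / 0.9893, rel=1e-9)


def test_deuterium_peaks_fall_below_cutoff():
    pattern = cf.isotope_pattern("H2", min_rel_abundance=0.01)
    assert len(pattern.peaks) == 1


def test_glucose_a1_abundance_matches_closed_form():
    # A+1 cluster of C6H12O6: 13C + 2H + 17O substitutions
    pattern = cf.isotope_pattern(
        "C6H12O6", min_rel_abundance=1e-6, merge_window=0.05
    )
    a1 = [r for m, r in pattern.peaks if abs(m - pattern.peaks[0][0] - 1.003) < 0.05]
    assert len(a1) == 1
    expected = (
        6 * ISOTOPES["C"][1][1] / ISOTOPES["C"][0][1]
        + 12 * ISOTOPES["H"][1][1] / ISOTOPES["H"][0][1]
        + 6 * ISOTOPES["O"][1][1] / ISOTOPES["O"][0][1]
    )
    assert a1[0] == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize("formula", ["C10H20O5S", "C5H5N5", "C2H6O", "C47H88O16P2"])
def test_unpruned_isotopologue_abundances_sum_to_one(formula):
    dist = cf.isotopologue_distribution(formula, prune=0.0)
    assert sum(p for _, p in dist) == pytest.approx(1.0, abs=1e-9)


def test_fine_structure_resolved_below_merge_window():
    # 34S vs 2×13C substitutions differ by ~11 mDa: resolved at the default
    # merge window, merged into one A+2 peak at a coarse one
    fine = cf.isotope_pattern("C10H20O5S", min_rel_abundance=1e-3)
    coarse = cf.isotope_pattern("C10H20O5S", min_rel_abundance=1e-3,
                                merge_window=0.05)
    assert len(fine.peaks) > len(coarse.peaks)


def test_pattern_invariants_enforced():
    with pytest.raises(ValueError):
        cf.IsotopePattern(peaks=((12.0, 0.5),), formula=cf.Formula({"C": 1}))
    with pytest.raises(ValueError):
        cf.IsotopePattern(
            peaks=((13.0, 1.0), (12.0, 0.5)), formula=cf.Formula({"C": 1})
        )


# ---------------------------------------------------------------------------
# Isotope verification
# ---------------------------------------------------------------------------


def test_verify_accepts_exact_containment():
    pattern = cf.isotope_pattern("C24H32O8", min_rel_abundance=0.01)
    observed = [(m, 1000.0 * r) for m, r in pattern.peaks]
    assert cf.verify_isotopes(pattern, observed, tol_ppm=0.5, floor=0.01)


def test_verify_rejects_missing_a1_peak():
    pattern = cf.isotope_pattern("C24H32O8", min_rel_abundance=0.01)
    observed = [(pattern.peaks[0][0], 1000.0)]  # monoisotopic peak only
    assert not cf.verify_isotopes(pattern, observed, tol_ppm=0.5, floor=0.01)


def test_verify_against_simulated_spectrum():
    true = cf.Formula.from_string("C7H15NO4S")
    decoy = cf.Formula.from_string("C8H11N2O4")
    spectrum = simulate_spectrum([true], ppm_jitter=0.2, seed=11)
    true_pattern = cf.isotope_pattern(true, min_rel_abundance=0.01).shifted("[M-H]-")
    decoy_pattern = cf.isotope_pattern(decoy, min_rel_abundance=0.01).shifted("[M-H]-")
    assert cf.verify_isotopes(true_pattern, spectrum, tol_ppm=0.5, floor=0.01)
    assert not cf.verify_isotopes(decoy_pattern, spectrum, tol_ppm=0.5, floor=0.01)


def test_verify_empty_spectrum_is_false():
    pattern = cf.isotope_pattern("C2H6O")
    assert not cf.verify_isotopes(pattern, np.empty((0, 2)))


# ---------------------------------------------------------------------------
# Elemental classes and van Krevelen
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "formula, expected",
    [
        ("C24H32O8", "CHO"),
        ("C7H15NO4S", "CHONS"),
        ("C17H20N4O2", "CHON"),
        ("C10H20O5S", "CHOS"),
        ("C47H88O16P2", "CHOP"),
        ("CH4", "other"),
        ("C14H34N6O", "CHON"),
    ],
)
def test_elemental_class(formula, expected):
    assert cf.elemental_class(formula) == expected


@pytest.mark.parametrize(
    "formula, oc, hc, cram",
    [
        ("C24H32O8", 8 / 24, 32 / 24, True),
        ("CH4", 0.0, 4.0, False),
        ("C2H5NO2", 1.0, 2.5, False),
    ],
)
def test_van_krevelen_ratios_and_cram_flag(formula, oc, hc, cram):
    got_oc, got_hc, got_cram = cf.van_krevelen(formula)
    assert got_oc == pytest.approx(oc)
    assert got_hc == pytest.approx(hc)
    assert got_cram is cram


def test_van_krevelen_rejects_carbon_free_formula():
    with pytest.raises(ValueError):
        cf.van_krevelen("H2O")
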