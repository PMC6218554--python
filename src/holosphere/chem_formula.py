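"""Exact-mass chemistry for untargeted metabolomics.

Everything needed to go from an accurate mass to a verified elemental formula:

* :class:`Formula` — an elemental composition over CHNOPS with Hill-notation
  round-tripping and monoisotopic mass.
* :class:`Adduct` — ESI adduct arithmetic (``[M-H]-``, ``[2M+NH4]+`` ...),
  electron-corrected.
* :func:`enumerate_formulas` — exhaustive search of the bounded CHNOPS lattice
  for formulas matching a mass within a ppm tolerance, with the classic
  ring-double-bond-equivalent and elemental-ratio plausibility filters.
* :func:`isotope_pattern` / :func:`verify_isotopes` — theoretical isotopic
  fine structure by per-element multinomial convolution, and the rule that a
  formula is only accepted when every theoretical isotope peak above an
  abundance floor is found in the measured spectrum.
* :func:`elemental_class` / :func:`van_krevelen` — the CHO/CHON/CHOS/...
  classification and H/C-vs-O/C coordinates used to map dissolved organic
  matter, including the carboxylic-rich-alicyclic-matter (CRAM) window.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .constants import ELECTRON_MASS, ELEMENTS, ISOTOPES, MONOISOTOPIC_MASS, PROTON_MASS

__all__ = [
    "Formula",
    "Adduct",
    "IsotopePattern",
    "CandidateAssignment",
    "monoisotopic_mass",
    "adduct_mz",
    "enumerate_formulas",
    "isotope_pattern",
    "isotopologue_distribution",
    "verify_isotopes",
    "elemental_class",
    "van_krevelen",
    "rdbe",
    "DEFAULT_BOUNDS",
]

#: Default per-element maximum counts for formula enumeration; generous enough
#: for small-molecule DOM in the 100–1000 Da window.
DEFAULT_BOUNDS: dict[str, int] = {"C": 60, "H": 100, "N": 10, "O": 20, "P": 3, "S": 5}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition over {C, H, N, O, P, S}.

    Immutable and hashable; serialises to Hill notation (carbon first,
    hydrogen second, remaining elements alphabetical).
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts):
        if isinstance(counts, Formula):
            counts = dict(counts.counts)
        items = {}
        for element, n in dict(counts).items():
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {element}: {n}")
            if n:
                items[element] = n
        if not items:
            raise ValueError("a formula must contain at least one atom")
        ordered = tuple(sorted(items.items(), key=lambda kv: _hill_key(kv[0])))
        object.__setattr__(self, "counts", ordered)

    @classmethod
    def from_string(cls, text: str) -> "Formula":
        """Parse Hill notation, e.g. ``"C24H32O8"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for element, n in other.counts:
            merged[element] = merged.get(element, 0) + n
        return Formula(merged)

    def __str__(self) -> str:
        parts = []
        for element, n in self.counts:
            parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Formula({self!s})"

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def _hill_key(element: str) -> tuple[int, str]:
    if element == "C":
        return (0, "")
    if element == "H":
        return (1, "")
    return (2, element)


def monoisotopic_mass(formula: Formula | str) -> float:
    """Monoisotopic mass in Da: each atom at its most abundant isotope."""
    if isinstance(formula, str):
        formula = Formula.from_string(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts)


def rdbe(formula: Formula) -> float:
    """Ring-plus-double-bond equivalents: C − H/2 + N/2 + P/2 + 1."""
    return (
        formula["C"]
        - formula["H"] / 2.0
        + formula["N"] / 2.0
        + formula["P"] / 2.0
        + 1.0
    )


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------

_ADDUCT_RE = re.compile(
    r"^\[(?P<multimer>\d*)M(?P<parts>(?:[+-][A-Za-z0-9]+)*)\]"
    r"(?P<charge>\d*)(?P<sign>[+-])$"
)


@dataclass(frozen=True)
class Adduct:
    """An ESI adduct such as ``[M-H]-`` or ``[2M+NH4]+``.

    ``mass_shift`` is the total mass added to ``multimer × M``, with the
    electron mass for the net charge already folded in, so that
    ``m/z = (multimer·M + mass_shift) / |charge|``.
    """

    name: str
    multimer: int
    charge: int
    mass_shift: float

    @classmethod
    def from_name(cls, name: str) -> "Adduct":
        match = _ADDUCT_RE.match(name.replace(" ", ""))
        if match is None:
            raise ValueError(f"cannot parse adduct {name!r}")
        multimer = int(match["multimer"] or 1)
        charge = int(match["charge"] or 1) * (1 if match["sign"] == "+" else -1)
        shift = 0.0
        for sign, group in re.findall(r"([+-])([A-Za-z0-9]+)", match["parts"]):
            group_mass = monoisotopic_mass(Formula.from_string(group))
            shift += group_mass if sign == "+" else -group_mass
        shift -= charge * ELECTRON_MASS
        return cls(name=name, multimer=multimer, charge=charge, mass_shift=shift)


#: Adducts the pipeline uses by default; negative mode is the FT-ICR default.
COMMON_ADDUCTS = {
    name: Adduct.from_name(name)
    for name in ("[M-H]-", "[M+H]+", "[M+NH4]+", "[2M+NH4]+", "[M+H+NH4]2+")
}


def adduct_mz(formula: Formula | str | float, adduct: Adduct | str) -> float:
    """m/z of an adduct ion: ``(multimer·M + mass_shift) / |charge|``.

    ``formula`` may also be a pre-computed neutral mass in Da.
    """
    if isinstance(adduct, str):
        adduct = COMMON_ADDUCTS.get(adduct) or Adduct.from_name(adduct)
    if adduct.charge == 0:
        raise ValueError("adduct charge must be nonzero")
    if isinstance(formula, (int, float)):
        neutral = float(formula)
    else:
        neutral = monoisotopic_mass(formula)
    return (adduct.multimer * neutral + adduct.mass_shift) / abs(adduct.charge)


# ---------------------------------------------------------------------------
# Formula enumeration
# ---------------------------------------------------------------------------


@dataclass
class CandidateAssignment:
    """One formula candidate explaining an observed mass."""

    formula: Formula
    ppm_error: float
    adduct: Adduct | None = None
    isotopes_verified: bool = False
    elemental_class: str = field(default="")
    rdbe: float = 0.0

    def __post_init__(self):
        if not self.elemental_class:
            self.elemental_class = elemental_class(self.formula)
        self.rdbe = rdbe(self.formula)


#: Refuse lattices larger than this many (C, N, O, P, S) grid points.
_LATTICE_SAFETY_LIMIT = 20_000_000


@lru_cache(maxsize=8)
def _cnops_grid(bounds: tuple[int, int, int, int, int]):
    """Meshgrid of partial masses over the (C, N, O, P, S) box, H excluded."""
    c_max, n_max, o_max, p_max, s_max = bounds
    axes = [
        np.arange(c_max + 1) * MONOISOTOPIC_MASS["C"],
        np.arange(n_max + 1) * MONOISOTOPIC_MASS["N"],
        np.arange(o_max + 1) * MONOISOTOPIC_MASS["O"],
        np.arange(p_max + 1) * MONOISOTOPIC_MASS["P"],
        np.arange(s_max + 1) * MONOISOTOPIC_MASS["S"],
    ]
    partial = (
        axes[0][:, None, None, None, None]
        + axes[1][None, :, None, None, None]
        + axes[2][None, None, :, None, None]
        + axes[3][None, None, None, :, None]
        + axes[4][None, None, None, None, :]
    )
    counts = np.indices(partial.shape)
    return partial, counts


def enumerate_formulas(
    mass: float,
    tol_ppm: float = 0.5,
    bounds: dict[str, int] | None = None,
    adduct: Adduct | str | None = None,
    require_rdbe_nonneg: bool = True,
    ratio_filters: bool = False,
) -> list[CandidateAssignment]:
    """All CHNOPS formulas matching a mass within ``tol_ppm``.

    The search runs over the full bounded lattice: carbon, nitrogen, oxygen,
    phosphorus and sulfur counts are gridded and the hydrogen count is solved
    from the mass residual, which is exhaustive because the ppm window is far
    narrower than one hydrogen mass.  When ``adduct`` is given, ``mass`` is
    interpreted as an observed ion m/z and the tolerance is applied on the
    ion-m/z scale.

    Candidates are ranked by \\|ppm error\\| ascending, ties broken by lower
    ring-double-bond equivalents, then Hill notation.

    Parameters
    ----------
    require_rdbe_nonneg:
        Keep only formulas with RDBE ≥ 0 (on by default).
    ratio_filters:
        Optional plausibility heuristics: H/C ∈ [0.2, 3.1], N/C ≤ 1.3,
        O/C ≤ 3, S/C ≤ 0.8 (off by default; they assume carbon-backbone
        chemistry).
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    if isinstance(adduct, str):
        adduct = COMMON_ADDUCTS.get(adduct) or Adduct.from_name(adduct)

    key = tuple(bounds.get(el, 0) for el in ("C", "N", "O", "P", "S"))
    lattice_size = math.prod(k + 1 for k in key)
    if lattice_size > _LATTICE_SAFETY_LIMIT:
        raise ValueError(
            f"element bounds span {lattice_size} lattice points, above the "
            f"safety limit of {_LATTICE_SAFETY_LIMIT}; tighten the bounds"
        )

    # Convert the ion m/z window to a neutral-mass window.
    if adduct is not None:
        neutral = (mass * abs(adduct.charge) - adduct.mass_shift) / adduct.multimer
        # tolerance stays on the ion-m/z scale
        tol_da = tol_ppm * 1e-6 * mass * abs(adduct.charge) / adduct.multimer
    else:
        neutral = mass
        tol_da = tol_ppm * 1e-6 * mass

    partial, counts = _cnops_grid(key)
    m_h = MONOISOTOPIC_MASS["H"]
    residual = neutral - partial
    h_base = np.floor(residual / m_h).astype(np.int64)

    out: list[CandidateAssignment] = []
    for h_counts in (h_base, h_base + 1):
        valid = (h_counts >= 0) & (h_counts <= bounds.get("H", 0))
        exact = partial + h_counts * m_h
        err_da = exact - neutral
        valid &= np.abs(err_da) <= tol_da
        if not valid.any():
            continue
        c, n, o, p, s = (cnt[valid] for cnt in counts)
        h = h_counts[valid]
        if require_rdbe_nonneg:
            keep = (c - h / 2.0 + n / 2.0 + p / 2.0 + 1.0) >= 0
            c, n, o, p, s, h = c[keep], n[keep], o[keep], p[keep], s[keep], h[keep]
        if ratio_filters:
            with np.errstate(divide="ignore", invalid="ignore"):
                keep = (
                    (c > 0)
                    & (h / c >= 0.2)
                    & (h / c <= 3.1)
                    & (n / c <= 1.3)
                    & (o / c <= 3.0)
                    & (s / c <= 0.8)
                )
            c, n, o, p, s, h = c[keep], n[keep], o[keep], p[keep], s[keep], h[keep]
        for ci, ni, oi, pi, si, hi in zip(c, n, o, p, s, h):
            formula = Formula(
                {"C": int(ci), "H": int(hi), "N": int(ni), "O": int(oi),
                 "P": int(pi), "S": int(si)}
            )
            if adduct is not None:
                theo = adduct_mz(formula, adduct)
                ppm = (mass - theo) / theo * 1e6
            else:
                ppm = (mass - monoisotopic_mass(formula)) / monoisotopic_mass(formula) * 1e6
            out.append(CandidateAssignment(formula=formula, ppm_error=ppm, adduct=adduct))

    out.sort(key=lambda cand: (abs(cand.ppm_error), cand.rdbe, str(cand.formula)))
    return out


# ---------------------------------------------------------------------------
# Isotopic fine structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopePattern:
    """Theoretical isotopologue peak list for one formula.

    ``peaks`` are (mass in Da, abundance relative to the base peak) with the
    base peak at exactly 1 and masses strictly increasing.
    """

    peaks: tuple[tuple[float, float], ...]
    formula: Formula

    def __post_init__(self):
        rels = [r for _, r in self.peaks]
        if not rels or abs(max(rels) - 1.0) > 1e-12:
            raise ValueError("base peak relative abundance must be 1")
        masses = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("peak masses must be strictly increasing")

    def shifted(self, adduct: Adduct | str) -> "IsotopePattern":
        """Pattern on the ion m/z scale for a monomeric adduct."""
        if isinstance(adduct, str):
            adduct = COMMON_ADDUCTS.get(adduct) or Adduct.from_name(adduct)
        if adduct.multimer != 1:
            raise ValueError("isotope-pattern shifting supports monomers only")
        z = abs(adduct.charge)
        peaks = tuple(((m + adduct.mass_shift) / z, r) for m, r in self.peaks)
        return IsotopePattern(peaks=peaks, formula=self.formula)


def _element_distribution(element: str, n: int, prune: float):
    """Isotopologue (mass, probability) list for ``n`` atoms of one element.

    Exact multinomial enumeration over heavy-isotope counts; compositions with
    probability below ``prune`` are dropped (``prune=0`` enumerates fully).
    """
    isotopes = ISOTOPES[element]
    if n == 0 or len(isotopes) == 1:
        return [(n * isotopes[0][0], 1.0)]
    heavy = isotopes[1:]
    m0, p0 = isotopes[0]
    out = []
    # iterate over counts of each heavy isotope; k0 is implied
    ranges = [range(n + 1) for _ in heavy]
    log_fact = [math.lgamma(i + 1) for i in range(n + 1)]
    for ks in itertools.product(*ranges):
        k_heavy = sum(ks)
        if k_heavy > n:
            continue
        k0 = n - k_heavy
        log_p = log_fact[n] - log_fact[k0] - sum(log_fact[k] for k in ks)
        log_p += k0 * math.log(p0)
        skip = False
        for k, (_, p) in zip(ks, heavy):
            if k:
                if p == 0.0:
                    skip = True
                    break
                log_p += k * math.log(p)
        if skip:
            continue
        prob = math.exp(log_p)
        if prune and prob < prune:
            continue
        mass = k0 * m0 + sum(k * m for k, (m, _) in zip(ks, heavy))
        out.append((mass, prob))
    return out


def isotopologue_distribution(
    formula: Formula | str, prune: float = 1e-12
) -> list[tuple[float, float]]:
    """Full isotopologue distribution (mass, probability), unmerged.

    Probabilities sum to 1 up to the pruning loss; with ``prune=0`` the
    enumeration is exact.  Sorted by mass.
    """
    if isinstance(formula, str):
        formula = Formula.from_string(formula)
    dist = [(0.0, 1.0)]
    for element, n in formula.counts:
        elem_dist = _element_distribution(element, n, prune)
        dist = [
            (m1 + m2, p1 * p2)
            for m1, p1 in dist
            for m2, p2 in elem_dist
            if not prune or p1 * p2 >= prune
        ]
    dist.sort()
    return dist


def isotope_pattern(
    formula: Formula | str,
    min_rel_abundance: float = 0.001,
    merge_window: float = 0.0002,
    prune: float = 1e-12,
) -> IsotopePattern:
    """Theoretical isotopic fine structure of a formula.

    Isotopologues closer than ``merge_window`` (Da) are aggregated into one
    peak at their abundance-weighted mean mass — 0.0002 Da is resolvable fine
    structure on a 12 T FT-ICR instrument.  Peaks below ``min_rel_abundance``
    of the base peak are dropped.
    """
    if not (0 < min_rel_abundance < 1):
        raise ValueError("min_rel_abundance must be in (0, 1)")
    if isinstance(formula, str):
        formula = Formula.from_string(formula)
    dist = isotopologue_distribution(formula, prune=prune)

    merged: list[list[float]] = []  # [sum(p*m), sum(p)]
    for mass, prob in dist:
        if merged and mass - merged[-1][0] / merged[-1][1] <= merge_window:
            merged[-1][0] += prob * mass
            merged[-1][1] += prob
        else:
            merged.append([prob * mass, prob])
    peaks = [(pm / p, p) for pm, p in merged]
    base = max(p for _, p in peaks)
    peaks = [(m, p / base) for m, p in peaks if p / base >= min_rel_abundance]
    # floating-point guard: re-pin the base peak to exactly 1
    peaks = [(m, min(p, 1.0)) for m, p in peaks]
    return IsotopePattern(peaks=tuple(peaks), formula=formula)


def verify_isotopes(
    pattern: IsotopePattern,
    observed: "np.ndarray | list",
    tol_ppm: float = 0.5,
    floor: float = 0.001,
) -> bool:
    """True iff every theoretical peak above ``floor`` is found in ``observed``.

    This is the all-or-nothing acceptance rule for ultra-high-resolution
    formula assignment: a formula is only trusted when the spectrum contains
    *all* of its predicted isotope peaks (those above the abundance floor)
    within the mass tolerance.  ``observed`` is a peak list of (m/z,
    intensity) rows or a bare m/z array.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        return False
    mz = obs[:, 0] if obs.ndim == 2 else obs
    for mass, rel in pattern.peaks:
        if rel < floor:
            continue
        if not np.any(np.abs(mz - mass) <= tol_ppm * 1e-6 * mass):
            return False
    return True


# ---------------------------------------------------------------------------
# Elemental classification
# ---------------------------------------------------------------------------

def elemental_class(formula: Formula | str) -> str:
    """CHO-family class token: CHO, CHON, CHOS, CHONS, CHOP, CHONP, CHOSP,
    CHONSP, or ``other`` when C, H or O is absent."""
    if isinstance(formula, str):
        formula = Formula.from_string(formula)
    if not (formula["C"] and formula["H"] and formula["O"]):
        return "other"
    token = "CHO"
    if formula["N"]:
        token += "N"
    if formula["S"]:
        token += "S"
    if formula["P"]:
        token += "P"
    return token


#: Van Krevelen window characteristic of carboxylic-rich alicyclic matter.
CRAM_HC_RANGE = (0.7, 1.5)
CRAM_OC_RANGE = (0.2, 0.7)


def van_krevelen(formula: Formula | str) -> tuple[float, float, bool]:
    """(O/C, H/C, is_CRAM_like) for one formula.

    The CRAM window — H/C in [0.7, 1.5] and O/C in [0.2, 0.7] — marks the
    refractory dissolved-organic-matter region typical of seawater.
    """
    if isinstance(formula, str):
        formula = Formula.from_string(formula)
    if formula["C"] == 0:
        raise ValueError("van Krevelen ratios need at least one carbon")
    oc = formula["O"] / formula["C"]
    hc = formula["H"] / formula["C"]
    cram = (
        CRAM_HC_RANGE[0] <= hc <= CRAM_HC_RANGE[1]
        and CRAM_OC_RANGE[0] <= oc <= CRAM_OC_RANGE[1]
    )
    return oc, hc, cram
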