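"""Fixed physical constants used throughout the package.

Atomic masses and isotopic abundances are IUPAC 2013 values, frozen here as
plain literals so that every mass computed by the package is bit-stable across
platforms and library versions.  Only the CHNOPS elements are supported: they
cover the dissolved-organic-matter space that ultra-high-resolution FT-ICR-MS
formula assignment targets.
"""

from __future__ import annotations

#: Elements supported by the formula machinery, in Hill order (C, H, then
#: alphabetical).
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "P", "S")

#: Monoisotopic (most-abundant-isotope) atomic masses in Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,  # exact by definition
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: Per-element isotope tables: (exact mass in Da, natural abundance fraction),
#: most abundant isotope first.  Abundances sum to 1 per element.
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": (
        (1.0078250319, 0.999885),
        (2.0141017781, 0.000115),
    ),
    "C": (
        (12.0, 0.9893),
        (13.0033548378, 0.0107),
    ),
    "N": (
        (14.0030740052, 0.99632),
        (15.0001088984, 0.00368),
    ),
    "O": (
        (15.9949146221, 0.99757),
        (16.9991315000, 0.00038),
        (17.9991604000, 0.00205),
    ),
    "P": (
        (30.97376151, 1.0),
    ),
    "S": (
        (31.97207069, 0.9499),
        (32.97145850, 0.0075),
        (33.96786683, 0.0425),
        (35.96708088, 0.0001),
    ),
}

#: Electron rest mass in Da; adduct mass shifts are electron-corrected.
ELECTRON_MASS: float = 0.0005485799

#: Proton mass in Da (H minus one electron); the canonical ESI charge carrier.
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS
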