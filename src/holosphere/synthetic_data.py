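"""Synthetic cohorts emulating the coral surface-to-seawater sampling design.

The generators reproduce, with known ground truth, the structure of the study
data: two coral species (a branching *Acropora*-like species with 8 colonies
and a massive *Platygyra*-like species with 10), seawater sampled at 0, 5 and
50 cm from each colony surface, half of the colonies visibly diseased.

Three generators cover the three pipeline inputs:

* :func:`simulate_feature_table` — an aligned LC-MS feature table in which a
  configurable fraction of features carries a planted exponential-decay
  concentration gradient ``background + A·exp(−k·d)`` over a flat seawater
  background, a further fraction is shifted in diseased colonies at the
  surface, and every feature's m/z derives from a real CHNOPS formula.
* :func:`simulate_spectrum` — an FT-ICR-style accurate-mass peak list for a
  set of known formulas, with isotopic fine structure and ppm-scale jitter.
* :func:`simulate_otu_table` — a 16S OTU count table dominated by a single
  *Pelagibacterales*-like taxon, with colony-specific surface communities that
  mix linearly into a common seawater community as distance grows.

Measurement noise is multiplicative log-normal (the standard model for LC-MS
peak intensities) and intensities below the detection floor are censored to
zero, mirroring the 500-count background cutoff used on the real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chem_formula as cf
from .feature_table import FeatureTable

__all__ = [
    "SimConfig",
    "simulate_feature_table",
    "simulate_spectrum",
    "simulate_otu_table",
    "random_formula",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study's sampling design: 2 species with 8 and 10
    colonies, distances 0/5/50 cm, half the colonies diseased, a 500-count
    detection floor, and 20% of features carrying a surface gradient.
    """

    n_species: int = 2
    colonies_per_species: tuple[int, ...] = (8, 10)
    fraction_diseased: float = 0.5
    distances: tuple[float, ...] = (0.0, 5.0, 50.0)
    n_features: int = 500
    fraction_gradient: float = 0.2
    #: Of the gradient features, the share with zero seawater background —
    #: these vanish below the detection floor at 50 cm, so with the defaults
    #: 1 − 0.2·0.6 = 88% of features are detectable at all three distances.
    fraction_background_free: float = 0.6
    decay_rate_range: tuple[float, float] = (0.05, 0.3)  # per cm
    #: Gradient amplitude at the surface, as a multiple of the feature's own
    #: seawater background (or of ``gradient_background_median`` for
    #: background-free features).
    gradient_gain_range: tuple[float, float] = (3.0, 10.0)
    #: Median seawater background of gradient molecules.  Holobiont-derived
    #: compounds are trace components near the detection floor in open water;
    #: keeping their amplitudes on this scale also keeps them a small share
    #: of total ion current, as in real data, so total-intensity
    #: normalization does not itself distort the planted gradients.
    gradient_background_median: float = 1500.0
    fraction_disease_marker: float = 0.03
    disease_effect: float = 2.0  # log2 fold-change at 0 cm
    noise_sigma: float = 0.2  # natural-log scale sd
    background_median: float = 1e4  # intensity counts
    background_spread: float = 0.5  # log-scale sd of per-feature backgrounds
    detection_floor: float = 500.0  # intensity counts
    rt_range: tuple[float, float] = (0.5, 12.0)  # minutes
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_diseased", "fraction_gradient",
                     "fraction_background_free", "fraction_disease_marker"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.n_species <= 0 or len(self.colonies_per_species) < self.n_species:
            raise ValueError("need a colony count for every species")
        if any(c <= 0 for c in self.colonies_per_species[: self.n_species]):
            raise ValueError("colony counts must be positive")
        if min(self.distances) != 0.0 or any(d < 0 for d in self.distances):
            raise ValueError("distances must be non-negative and include 0")


_SPECIES_NAMES = ("Acropora", "Platygyra", "SpeciesC", "SpeciesD")


def random_formula(rng: np.random.Generator, mass_range=(100.0, 1000.0)) -> cf.Formula:
    """A random chemically plausible CHNOPS formula in a mass window.

    Draws a carbon skeleton, decorates it with heteroatoms, then picks a
    hydrogen count with the right parity so the ring-double-bond equivalent
    is a non-negative integer (a closed-shell neutral molecule).
    """
    lo, hi = mass_range
    for _ in range(1000):
        c_hi = min(max(4, int(hi / 13)), cf.DEFAULT_BOUNDS["C"])
        c = int(rng.integers(max(2, int(lo / 25)), c_hi + 1))
        n = int(rng.integers(0, 5))
        o = int(rng.integers(0, 11))
        p = int(rng.integers(0, 2)) if rng.random() < 0.1 else 0
        s = int(rng.integers(0, 2)) if rng.random() < 0.15 else 0
        h_max = min(2 * c + n + 2, cf.DEFAULT_BOUNDS["H"])  # saturated limit
        # H parity must match N+P parity for integer RDBE
        parity = (n + p) % 2
        h_choices = [h for h in range(parity, h_max + 1, 2)
                     if c - h / 2 + n / 2 + p / 2 + 1 >= 0]
        if not h_choices:
            continue
        h = int(rng.choice(h_choices))
        if h == 0:
            continue
        formula = cf.Formula({"C": c, "H": h, "N": n, "O": o, "P": p, "S": s})
        if lo <= formula.mass <= hi:
            return formula
    raise RuntimeError("could not draw a formula in the requested mass window")


def simulate_feature_table(config: SimConfig) -> tuple[FeatureTable, pd.DataFrame]:
    """Generate one aligned feature table per the cohort design, plus truth.

    Returns the feature table (all species pooled; one sample per colony and
    distance) and a ground-truth frame indexed by feature id with columns
    ``is_gradient``, ``is_disease_marker``, ``direction``, ``background``,
    ``A``, ``k``, ``formula``.

    Gradient amplitudes and disease shifts are shared across species —
    emulating holobiont products common to both corals — so cross-species
    intersection logic is exercised end-to-end.
    """
    rng = np.random.default_rng(config.seed)
    n_feat = config.n_features

    # --- per-feature truth -------------------------------------------------
    n_grad = int(round(config.fraction_gradient * n_feat))
    n_marker = int(round(config.fraction_disease_marker * n_feat))
    is_gradient = np.zeros(n_feat, dtype=bool)
    is_gradient[:n_grad] = True
    n_bg_free = int(round(config.fraction_background_free * n_grad))
    background_free = np.zeros(n_feat, dtype=bool)
    background_free[:n_bg_free] = True
    # disease markers drawn from the non-gradient block so the two planted
    # effects never collide on one feature
    is_marker = np.zeros(n_feat, dtype=bool)
    if n_marker > n_feat - n_grad:
        raise ValueError("too many disease markers for the non-gradient pool")
    is_marker[n_grad: n_grad + n_marker] = True
    direction = np.where(rng.random(n_feat) < 0.5, "up-in-diseased", "up-in-healthy")
    direction[~is_marker] = ""

    background = config.background_median * np.exp(
        rng.normal(0.0, config.background_spread, n_feat)
    )
    # gradient molecules sit near the detection floor in open seawater
    background[is_gradient] *= (
        config.gradient_background_median / config.background_median
    )
    background[background_free] = 0.0
    gain = rng.uniform(*config.gradient_gain_range, n_feat)
    amplitude_scale = np.where(
        background > 0, background, config.gradient_background_median
    )
    amplitude = np.where(is_gradient, gain * amplitude_scale, 0.0)
    decay = np.where(
        is_gradient, rng.uniform(*config.decay_rate_range, n_feat), 0.0
    )

    formulas = [random_formula(rng) for _ in range(n_feat)]
    mz = np.array([cf.adduct_mz(f, "[M-H]-") for f in formulas])
    rt = rng.uniform(*config.rt_range, n_feat)
    feature_ids = [f"F{i:05d}" for i in range(n_feat)]

    truth = pd.DataFrame(
        {
            "is_gradient": is_gradient,
            "is_disease_marker": is_marker,
            "direction": direction,
            "background": background,
            "A": amplitude,
            "k": decay,
            "formula": [str(f) for f in formulas],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    # --- samples -----------------------------------------------------------
    sample_rows = []
    for sp in range(config.n_species):
        species = _SPECIES_NAMES[sp]
        n_colonies = config.colonies_per_species[sp]
        n_diseased = int(round(config.fraction_diseased * n_colonies))
        for colony in range(n_colonies):
            health = "diseased" if colony < n_diseased else "healthy"
            for d in config.distances:
                sample_rows.append(
                    {
                        "sample_id": f"{species}_c{colony:02d}_d{int(d):02d}",
                        "species": species,
                        "colony": f"{species}_c{colony:02d}",
                        "distance": float(d),
                        "health": health,
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    # --- intensities -------------------------------------------------------
    dist = samples["distance"].to_numpy()[None, :]  # (1, n_samples)
    mean = background[:, None] + amplitude[:, None] * np.exp(-decay[:, None] * dist)
    # disease shift applies at the surface only
    at_surface = (dist == 0.0)
    diseased = (samples["health"] == "diseased").to_numpy()[None, :]
    shift = np.where(
        direction[:, None] == "up-in-diseased",
        2.0 ** config.disease_effect,
        np.where(direction[:, None] == "up-in-healthy",
                 2.0 ** -config.disease_effect, 1.0),
    )
    mean = np.where(at_surface & diseased, mean * shift, mean)

    if config.noise_sigma > 0:
        noise = np.exp(rng.normal(0.0, config.noise_sigma, mean.shape))
    else:
        noise = 1.0
    intensity = mean * noise
    intensity[intensity < config.detection_floor] = 0.0

    features = pd.DataFrame(
        {"mz": mz, "rt": rt}, index=pd.Index(feature_ids, name="feature_id")
    )
    table = FeatureTable(
        features=features,
        samples=samples,
        intensities=pd.DataFrame(intensity, index=features.index, columns=samples.index),
    )
    return table, truth


def simulate_spectrum(
    formulas,
    ppm_jitter: float = 0.0,
    include_isotopes: bool = True,
    seed: int | None = 0,
    adduct: str = "[M-H]-",
    isotope_floor: float = 0.001,
    base_intensity: float = 1e6,
) -> np.ndarray:
    """Accurate-mass peak list (m/z, intensity) for known formulas.

    Each formula contributes its deprotonated ion (default) at ``base_intensity``
    plus, when ``include_isotopes``, its full isotopic fine structure above
    ``isotope_floor``.  Every peak's m/z is perturbed by Gaussian noise with
    standard deviation ``ppm_jitter`` (in ppm).
    """
    if ppm_jitter < 0:
        raise ValueError("ppm_jitter must be non-negative")
    rng = np.random.default_rng(seed)
    peaks = []
    for formula in formulas:
        if isinstance(formula, str):
            formula = cf.Formula.from_string(formula)
        if include_isotopes:
            pattern = cf.isotope_pattern(formula, min_rel_abundance=isotope_floor)
            ion = pattern.shifted(adduct)
            for mass, rel in ion.peaks:
                peaks.append((mass, rel * base_intensity))
        else:
            peaks.append((cf.adduct_mz(formula, adduct), base_intensity))
    out = np.array(sorted(peaks), dtype=float)
    if ppm_jitter > 0 and out.size:
        out[:, 0] *= 1.0 + rng.normal(0.0, ppm_jitter * 1e-6, len(out))
    return out


def simulate_otu_table(
    n_taxa: int = 100,
    dominant_fraction: float = 0.98,
    distance_mixing: float = 0.5,
    n_colonies: int = 8,
    distances=(0.0, 5.0, 50.0),
    depth: int = 100_000,
    species: str = "Acropora",
    seed: int | None = 0,
    multinomial: bool = True,
):
    """OTU count table with a dominant taxon and a distance-decaying community.

    One *Pelagibacterales*-like taxon takes ``dominant_fraction`` of every
    library.  The remaining community is colony-specific at the surface and is
    linearly mixed toward one shared seawater community in proportion to
    physical distance: the mixing coefficient at distance ``d`` is
    ``distance_mixing · d / max(distances)``, so ``distance_mixing = 1``
    makes the farthest sample pure seawater while the 5 cm halo stays close
    to the surface community — the structure behind the near/far correlation
    contrast.  Counts are multinomial draws of ``depth`` reads
    (``multinomial=False`` writes the rounded expected counts instead, for
    noise-free checks).

    Returns an :class:`~holosphere.community.OTUTable`.
    """
    from .community import OTUTable  # deferred: community imports nothing back

    if not 0 <= dominant_fraction < 1:
        raise ValueError("dominant_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_rest = n_taxa - 1
    taxa_ids = [f"OTU{i:04d}" for i in range(n_taxa)]
    taxonomy = ["Pelagibacteraceae"] + [f"Family{i:03d}" for i in range(1, n_taxa)]

    # community profiles over the non-dominant taxa (Dirichlet keeps them
    # positive and realistically uneven)
    seawater = rng.dirichlet(np.full(n_rest, 0.3))
    d_max = max(max(distances), 1e-12)

    counts = {}
    meta_rows = []
    for colony in range(n_colonies):
        surface = rng.dirichlet(np.full(n_rest, 0.3))
        for d in distances:
            alpha = distance_mixing * d / d_max
            rest = (1.0 - alpha) * surface + alpha * seawater
            probs = np.concatenate(
                [[dominant_fraction], (1.0 - dominant_fraction) * rest]
            )
            sample_id = f"{species}_c{colony:02d}_d{int(d):02d}"
            if multinomial:
                counts[sample_id] = rng.multinomial(depth, probs)
            else:
                counts[sample_id] = np.round(probs * depth).astype(int)
            meta_rows.append(
                {"sample_id": sample_id, "species": species,
                 "colony": f"{species}_c{colony:02d}", "distance": float(d)}
            )

    taxa = pd.DataFrame(
        {"taxonomy": taxonomy}, index=pd.Index(taxa_ids, name="otu_id")
    )
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    count_df = pd.DataFrame(counts, index=taxa.index)
    return OTUTable(taxa=taxa, samples=samples, counts=count_df)
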