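"""Aligned LC-MS feature tables: container, I/O, filtering and set logic.

A :class:`FeatureTable` bundles the three frames every downstream stage needs:
feature descriptors (m/z, retention time), sample metadata (species, colony,
distance from the coral surface, health state) and the features × samples
intensity matrix, where 0 means "not detected".

The operations implement the study's data-reduction rules: the 500-count
background cutoff, the FT-ICR occurrence filter (masses present in ≥50% of
samples, aligned at 0.01 ppm), replicate-majority presence calls per distance,
the three-distance Venn partition, and cross-species feature matching by
mutual nearest neighbours in (m/z, RT).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "apply_noise_cutoff",
    "occurrence_filter",
    "presence_calls",
    "venn_partition",
    "match_features",
]


@dataclass(frozen=True)
class FeatureTable:
    """Features × samples intensity matrix with metadata.

    ``features``: indexed by feature id, columns ``mz`` (Da) and ``rt``
    (minutes).  ``samples``: indexed by sample id, columns ``species``,
    ``colony``, ``distance`` (cm) and optionally ``health``.
    ``intensities``: non-negative, aligned to both indices.
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self):
        if not self.features.index.is_unique:
            raise ValueError("feature ids must be unique")
        if not self.samples.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.intensities.index.equals(self.features.index):
            raise ValueError("intensity rows must match the feature index")
        if not self.intensities.columns.equals(self.samples.index):
            raise ValueError("intensity columns must match the sample index")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        for column in ("species", "distance"):
            if column not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {column!r}")
            if self.samples[column].isna().any():
                raise ValueError(f"sample metadata column {column!r} has gaps")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_features(self, feature_ids) -> "FeatureTable":
        return replace(
            self,
            features=self.features.loc[feature_ids],
            intensities=self.intensities.loc[feature_ids],
        )

    def subset_samples(self, mask_or_ids) -> "FeatureTable":
        samples = self.samples.loc[mask_or_ids]
        return replace(
            self, samples=samples, intensities=self.intensities[samples.index]
        )

    def for_species(self, species: str) -> "FeatureTable":
        return self.subset_samples(self.samples["species"] == species)

    # -- I/O ---------------------------------------------------------------

    def write(self, directory: str | Path, prefix: str = "features") -> None:
        """Write the table as three TSV files under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(directory / f"{prefix}.features.tsv", sep="\t")
        self.samples.to_csv(directory / f"{prefix}.samples.tsv", sep="\t")
        self.intensities.to_csv(directory / f"{prefix}.intensities.tsv", sep="\t")

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "features") -> "FeatureTable":
        directory = Path(directory)
        features = pd.read_csv(
            directory / f"{prefix}.features.tsv", sep="\t", index_col=0
        )
        samples = pd.read_csv(
            directory / f"{prefix}.samples.tsv", sep="\t", index_col=0
        )
        intensities = pd.read_csv(
            directory / f"{prefix}.intensities.tsv", sep="\t", index_col=0
        )
        intensities.index.name = features.index.name
        intensities.columns.name = samples.index.name
        return cls(features=features, samples=samples, intensities=intensities)


def apply_noise_cutoff(table: FeatureTable, cutoff: float = 500.0) -> FeatureTable:
    """Censor intensities below ``cutoff`` to 0 and drop all-zero features.

    500 counts is the background-noise cutoff applied to the study's LC-MS
    data; intensities strictly below the cutoff are treated as not detected.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    censored = table.intensities.where(table.intensities >= cutoff, 0.0)
    keep = censored.sum(axis=1) > 0
    return replace(
        table,
        features=table.features.loc[keep],
        intensities=censored.loc[keep],
    )


def occurrence_filter(
    peaklists, min_fraction: float = 0.5, align_tol_ppm: float = 0.01
):
    """Align FT-ICR peak lists and keep masses seen in enough samples.

    Masses from all lists are clustered by greedy single linkage within
    ``align_tol_ppm`` (sorted-order sweep: a peak joins the current cluster
    while it is within tolerance of the cluster's running mean).  Clusters
    detected in at least ``min_fraction`` of the input lists (boundary
    inclusive) are retained and represented by their intensity-weighted mean
    mass.

    Parameters
    ----------
    peaklists:
        Sequence of (n, 2+) arrays with columns m/z, intensity[, S/N].

    Returns
    -------
    DataFrame with columns ``mass``, ``n_lists``, ``fraction`` — one row per
    retained aligned mass, sorted by mass.
    """
    if len(peaklists) == 0:
        raise ValueError("need at least one peak list")
    rows = []
    for i, peaks in enumerate(peaklists):
        arr = np.atleast_2d(np.asarray(peaks, dtype=float))
        for mz, inten in arr[:, :2]:
            rows.append((mz, inten, i))
    rows.sort()

    clusters: list[dict] = []
    for mz, inten, src in rows:
        if clusters:
            c = clusters[-1]
            mean = c["wsum"] / c["isum"] if c["isum"] else np.mean(c["masses"])
            if abs(mz - mean) <= align_tol_ppm * 1e-6 * mean:
                c["masses"].append(mz)
                c["wsum"] += mz * inten
                c["isum"] += inten
                c["sources"].add(src)
                continue
        clusters.append(
            {"masses": [mz], "wsum": mz * inten, "isum": inten, "sources": {src}}
        )

    n_lists = len(peaklists)
    out = []
    for c in clusters:
        frac = len(c["sources"]) / n_lists
        if frac >= min_fraction:
            mass = c["wsum"] / c["isum"] if c["isum"] else float(np.mean(c["masses"]))
            out.append((mass, len(c["sources"]), frac))
    return pd.DataFrame(out, columns=["mass", "n_lists", "fraction"])


def presence_calls(
    table: FeatureTable, min_replicate_fraction: float = 0.5
) -> pd.DataFrame:
    """Per-feature, per-distance boolean presence calls.

    A feature is "present" at a distance when it is detected (nonzero) in at
    least ``min_replicate_fraction`` of that distance group's samples.  The
    table is assumed to hold one species (group replicates are colonies);
    call :meth:`FeatureTable.for_species` first on pooled tables.

    Returns a DataFrame indexed like the features with one boolean column per
    distance.
    """
    calls = {}
    for distance, group in table.samples.groupby("distance"):
        block = table.intensities[group.index]
        calls[distance] = (block > 0).mean(axis=1) >= min_replicate_fraction
    return pd.DataFrame(calls).sort_index(axis=1)


def venn_partition(calls: pd.DataFrame) -> dict[str, int]:
    """Counts of features per region of the three-distance Venn diagram.

    ``calls`` must have exactly three boolean distance columns.  Region keys
    name the distances, e.g. ``"0"``, ``"0&5"``, ``"0&5&50"``; features absent
    everywhere are not counted in any region.
    """
    if calls.shape[1] != 3:
        raise ValueError("venn_partition expects calls over exactly 3 distances")
    labels = [_fmt_distance(c) for c in calls.columns]
    values = calls.to_numpy(dtype=bool)
    regions: dict[str, int] = {}
    for pattern in ((1, 0, 0), (0, 1, 0), (0, 0, 1),
                    (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)):
        key = "&".join(l for l, bit in zip(labels, pattern) if bit)
        regions[key] = int((values == np.array(pattern, dtype=bool)).all(axis=1).sum())
    return regions


def _fmt_distance(value) -> str:
    value = float(value)
    return str(int(value)) if value == int(value) else str(value)


def match_features(
    table_a: FeatureTable,
    table_b: FeatureTable,
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.2,
) -> pd.DataFrame:
    """Cross-cohort feature matching by mutual nearest neighbours.

    Two features match when they lie within both the m/z and RT tolerances
    and each is the other's nearest candidate (by ppm distance, RT distance
    as tie-break).  Mutuality prevents chains: every feature appears in at
    most one pair.

    Returns a DataFrame with columns ``id_a``, ``id_b``, ``ppm``, ``delta_rt``,
    sorted by ``id_a``.
    """
    fa, fb = table_a.features, table_b.features
    mz_a = fa["mz"].to_numpy()[:, None]
    mz_b = fb["mz"].to_numpy()[None, :]
    ppm = np.abs(mz_a - mz_b) / ((mz_a + mz_b) / 2) * 1e6
    drt = np.abs(fa["rt"].to_numpy()[:, None] - fb["rt"].to_numpy()[None, :])
    ok = (ppm <= mz_tol_ppm) & (drt <= rt_tol_min)
    cost = np.where(ok, ppm + 1e-9 * drt, np.inf)

    rows = []
    if ok.any():
        best_for_a = np.argmin(cost, axis=1)
        best_for_b = np.argmin(cost, axis=0)
        for i, j in enumerate(best_for_a):
            if np.isfinite(cost[i, j]) and best_for_b[j] == i:
                rows.append(
                    (fa.index[i], fb.index[j], float(ppm[i, j]), float(drt[i, j]))
                )
    out = pd.DataFrame(rows, columns=["id_a", "id_b", "ppm", "delta_rt"])
    return out.sort_values("id_a", ignore_index=True)
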