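"""Microbial-community structure around coral colonies.

Works on 16S OTU count tables with per-sample distance metadata.  The
analysis mirrors the bacterial side of the holosphere question: after
removing the overwhelmingly dominant *Pelagibacterales* fraction (97–99% of
marine surface-water reads), does the residual community at the coral
surface stay more similar to the 5 cm halo than open seawater does?

Similarity is quantified as the Pearson correlation between each distance's
OTU relative-abundance vector and the 5 cm reference vector, computed per
colony, and the near/far contrast is tested with a two-sided pooled-variance
(Student) t-test across colonies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OTUTable",
    "remove_taxon",
    "relative_abundance",
    "top_n_composition",
    "distance_correlation",
    "compare_correlation_groups",
]


@dataclass(frozen=True)
class OTUTable:
    """Taxa × samples count table with taxonomy and distance metadata.

    ``taxa``: indexed by OTU id with a ``taxonomy`` column (family level).
    ``samples``: indexed by sample id with ``species``, ``distance`` and
    optionally ``colony``.  ``counts``: non-negative integers.
    """

    taxa: pd.DataFrame
    samples: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self):
        if not self.counts.index.equals(self.taxa.index):
            raise ValueError("count rows must match the taxa index")
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("count columns must match the sample index")
        values = self.counts.to_numpy()
        if (values < 0).any() or not np.allclose(values, np.round(values)):
            raise ValueError("counts must be non-negative integers")
        if "distance" not in self.samples.columns:
            raise ValueError("sample metadata lacks a 'distance' column")

    def write(self, directory: str | Path, prefix: str = "otus") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.taxa.to_csv(directory / f"{prefix}.taxa.tsv", sep="\t")
        self.samples.to_csv(directory / f"{prefix}.samples.tsv", sep="\t")
        self.counts.to_csv(directory / f"{prefix}.counts.tsv", sep="\t")

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "otus") -> "OTUTable":
        directory = Path(directory)
        return cls(
            taxa=pd.read_csv(directory / f"{prefix}.taxa.tsv", sep="\t", index_col=0),
            samples=pd.read_csv(
                directory / f"{prefix}.samples.tsv", sep="\t", index_col=0
            ),
            counts=pd.read_csv(
                directory / f"{prefix}.counts.tsv", sep="\t", index_col=0
            ),
        )


def remove_taxon(table: OTUTable, label: str) -> OTUTable:
    """Drop all OTUs whose taxonomy string equals ``label`` exactly.

    An absent label warns and returns the table unchanged (the caller may be
    iterating over cohorts where the dominant taxon was already filtered).
    """
    mask = table.taxa["taxonomy"] == label
    if not mask.any():
        warnings.warn(f"taxonomy label {label!r} not present; table unchanged")
        return table
    keep = table.taxa.index[~mask]
    return replace(table, taxa=table.taxa.loc[keep], counts=table.counts.loc[keep])


def relative_abundance(table: OTUTable) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1)."""
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("samples with zero total counts")
    return table.counts.div(totals, axis=1)


def top_n_composition(table: OTUTable, n: int = 10) -> pd.DataFrame:
    """Relative-abundance table of the ``n`` most abundant OTUs.

    Ranking is by total relative abundance across all samples, ties broken
    by OTU id; all remaining taxa are aggregated into an ``"other"`` row.
    """
    if len(table.taxa) < n:
        raise ValueError(f"table has fewer than {n} taxa")
    rel = relative_abundance(table)
    order = (
        rel.sum(axis=1)
        .to_frame("total")
        .assign(otu=rel.index)
        .sort_values(["total", "otu"], ascending=[False, True])
        .index
    )
    top = list(order[:n])
    out = rel.loc[top]
    rest = rel.drop(index=top).sum(axis=0)
    if len(table.taxa) > n:
        out = pd.concat([out, rest.to_frame("other").T])
    return out


def distance_correlation(
    table: OTUTable,
    reference_distance: float = 5.0,
    method: str = "pearson",
    per_colony: bool = True,
) -> pd.DataFrame:
    """Correlation of each distance's OTU profile with the reference distance.

    Relative-abundance vectors are compared with Pearson product-moment
    correlation by default (``method="spearman"`` switches to rank
    correlation).  With ``per_colony`` the comparison is within each colony
    (reference = the colony's own 5 cm sample); otherwise all samples are
    compared against the mean reference profile.  Self-comparisons give
    r = 1 exactly.  Zero-variance profiles yield NaN with a warning.

    Returns a DataFrame with columns ``colony``, ``distance``, ``r``.
    """
    rel = relative_abundance(table)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    def _r(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn("zero-variance abundance vector; correlation undefined")
            return float("nan")
        if np.array_equal(x, y):
            return 1.0
        return float(corr(x, y).statistic)

    rows = []
    if per_colony and "colony" in table.samples.columns:
        for colony, group in table.samples.groupby("colony"):
            ref_ids = group.index[group["distance"] == reference_distance]
            if len(ref_ids) == 0:
                raise ValueError(
                    f"colony {colony!r} has no sample at {reference_distance} cm"
                )
            ref = rel[ref_ids].mean(axis=1).to_numpy()
            for sample_id, meta in group.iterrows():
                rows.append(
                    {
                        "colony": colony,
                        "distance": float(meta["distance"]),
                        "r": _r(rel[sample_id].to_numpy(), ref),
                    }
                )
    else:
        ref_ids = table.samples.index[
            table.samples["distance"] == reference_distance
        ]
        if len(ref_ids) == 0:
            raise ValueError(f"no sample at reference distance {reference_distance}")
        ref = rel[ref_ids].mean(axis=1).to_numpy()
        for sample_id, meta in table.samples.iterrows():
            rows.append(
                {
                    "colony": meta.get("colony", sample_id),
                    "distance": float(meta["distance"]),
                    "r": _r(rel[sample_id].to_numpy(), ref),
                }
            )
    return pd.DataFrame(rows)


def compare_correlation_groups(r_near, r_far) -> float:
    """Two-sided pooled-variance (Student) t-test between correlation groups.

    ``r_near`` are the per-colony r(0 cm, 5 cm) values, ``r_far`` the
    r(50 cm, 5 cm) values of the same species.
    """
    a = np.asarray(r_near, dtype=float)
    b = np.asarray(r_far, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
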