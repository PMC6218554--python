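"""Cross-species discovery of coral-disease indicator molecules.

Candidate indicators are found in two stages, mirroring the white-syndrome
comparison on the real cohorts:

1. **Screen** (:func:`screen_health`): within one species, only surface
   (0 cm) samples are compared between healthy and diseased colonies —
   disease-linked metabolites are expected to concentrate at the surface.
   The per-feature test is a two-group one-way ANOVA (the F-test equivalent
   of a pooled t-test) on log-normalized intensities at α = 0.038.
2. **Intersect** (:func:`intersect_indicators`): features matched across the
   two species are kept when both species pass the screen *with the same
   direction of change*, and each survivor is annotated with a confirmatory
   Welch-test tier: strict (p ≤ 0.00059), loose (p < 0.0082) or none.
   Candidates whose Welch confirmation reaches at least the loose tier in
   both species are the final indicator calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .feature_table import FeatureTable
from .gradient_analysis import normalize, welch_test, _log

__all__ = [
    "screen_health",
    "intersect_indicators",
    "ALPHA_SCREEN",
    "ALPHA_CONFIRM_STRICT",
    "ALPHA_CONFIRM_LOOSE",
]

ALPHA_SCREEN = 0.038
ALPHA_CONFIRM_STRICT = 0.00059
ALPHA_CONFIRM_LOOSE = 0.0082


def screen_health(
    table: FeatureTable,
    species: str | None = None,
    normalized: bool = False,
) -> pd.DataFrame:
    """Healthy-vs-diseased screen over surface samples of one species.

    Returns a DataFrame indexed by feature id with columns ``p`` (two-group
    ANOVA on log intensities), ``welch_p`` (the confirmatory unequal-variance
    test on the same groups), ``direction`` (``"up-in-diseased"`` /
    ``"up-in-healthy"``, empty when the means are identical) and ``log2_fc``
    (diseased over healthy, on detected intensities + 1).
    """
    if species is not None:
        table = table.for_species(species)
    if "health" not in table.samples.columns:
        raise ValueError("sample metadata lacks a 'health' column")
    table = table.subset_samples(table.samples["distance"] == 0.0)
    if not normalized:
        table = normalize(table)
    healthy = table.samples.index[table.samples["health"] == "healthy"]
    diseased = table.samples.index[table.samples["health"] == "diseased"]
    if len(healthy) < 2 or len(diseased) < 2:
        raise ValueError("need at least 2 healthy and 2 diseased colonies")

    h = table.intensities[healthy].to_numpy()
    d = table.intensities[diseased].to_numpy()
    records = []
    for row, feature_id in enumerate(table.features.index):
        lh, ld = _log(h[row]), _log(d[row])
        p = _two_group_anova_p(lh, ld)
        delta = float(np.mean(ld) - np.mean(lh))
        direction = (
            "" if delta == 0
            else "up-in-diseased" if delta > 0
            else "up-in-healthy"
        )
        records.append(
            {
                "feature_id": feature_id,
                "p": p,
                "welch_p": welch_test(d[row], h[row]),
                "direction": direction,
                "log2_fc": delta / np.log(2.0),
            }
        )
    return pd.DataFrame.from_records(records).set_index("feature_id")


def _two_group_anova_p(a: np.ndarray, b: np.ndarray) -> float:
    """One-way ANOVA with two groups == pooled-variance t-test (F = t²)."""
    from scipy import stats

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.f_oneway(a, b).pvalue)


def intersect_indicators(
    screen_a: pd.DataFrame,
    screen_b: pd.DataFrame,
    matches: pd.DataFrame,
    alpha_screen: float = ALPHA_SCREEN,
    alpha_confirm_strict: float = ALPHA_CONFIRM_STRICT,
    alpha_confirm_loose: float = ALPHA_CONFIRM_LOOSE,
) -> pd.DataFrame:
    """Shared indicator candidates across two species.

    ``matches`` comes from :func:`holosphere.feature_table.match_features`
    (columns ``id_a``, ``id_b``).  A matched pair survives when both species'
    screening p-values pass ``alpha_screen`` with the same direction.  Each
    survivor is annotated with its confirmatory Welch tier — ``"strict"``
    when both species' Welch p ≤ ``alpha_confirm_strict``, ``"loose"`` when
    both are < ``alpha_confirm_loose``, else ``"none"`` — and ``confirmed``
    is true for tiers at loose or better.  Bonferroni-adjusted screening
    p-values (times the number of matched pairs, capped at 1) are reported
    alongside the raw ones.

    Rows are ordered by the product of the two screening p-values.
    """
    rows = []
    n_pairs = max(len(matches), 1)
    for pair in matches.itertuples(index=False):
        if pair.id_a not in screen_a.index or pair.id_b not in screen_b.index:
            continue
        a = screen_a.loc[pair.id_a]
        b = screen_b.loc[pair.id_b]
        if a["p"] > alpha_screen or b["p"] > alpha_screen:
            continue
        if a["direction"] != b["direction"] or a["direction"] == "":
            continue
        welch_max = max(a["welch_p"], b["welch_p"])
        if welch_max <= alpha_confirm_strict:
            tier = "strict"
        elif welch_max < alpha_confirm_loose:
            tier = "loose"
        else:
            tier = "none"
        rows.append(
            {
                "id_a": pair.id_a,
                "id_b": pair.id_b,
                "direction": a["direction"],
                "p_a": a["p"],
                "p_b": b["p"],
                "p_a_bonferroni": min(a["p"] * n_pairs, 1.0),
                "p_b_bonferroni": min(b["p"] * n_pairs, 1.0),
                "welch_p_a": a["welch_p"],
                "welch_p_b": b["welch_p"],
                "log2_fc_a": a["log2_fc"],
                "log2_fc_b": b["log2_fc"],
                "tier": tier,
                "confirmed": tier != "none",
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "id_a", "id_b", "direction", "p_a", "p_b",
            "p_a_bonferroni", "p_b_bonferroni", "welch_p_a", "welch_p_b",
            "log2_fc_a", "log2_fc_b", "tier", "confirmed",
        ],
    )
    if len(out):
        out = out.assign(_order=out["p_a"] * out["p_b"]).sort_values(
            ["_order", "id_a"], ignore_index=True
        ).drop(columns="_order")
    return out
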