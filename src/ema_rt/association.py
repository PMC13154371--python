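"""Spearman screen between EMA-derived features and symptom-change scores.

Every feature column is correlated with each of the four change scores
(d_gds15, d_cesdr, d_phq9, d_bai) using Spearman's rank correlation with
average ranks for ties and pairwise-complete deletion.  No multiple-testing
correction is applied — the screen is exploratory and the emitted table
annotates per-cell significance at .05/.01/.001 with stars.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

OUTCOMES = ("d_gds15", "d_cesdr", "d_phq9", "d_bai")
MIN_PAIRS = 3


def correlation_matrix(features: pd.DataFrame, changes: pd.DataFrame,
                       outcomes=OUTCOMES) -> tuple[pd.DataFrame, dict]:
    """Spearman rho and two-sided p per (feature, outcome) cell.

    Cells with fewer than 3 complete pairs are omitted (audited); constant
    features yield an undefined rho, flagged rather than dropped.
    """
    merged = features.merge(changes, on="subject_id", how="inner")
    feat_cols = [c for c in features.columns if c != "subject_id"]
    rows, audit = [], {"skipped_small_n": [], "undefined_rho": []}
    for feat in feat_cols:
        for out in outcomes:
            pair = merged[[feat, out]].dropna()
            n = len(pair)
            if n < MIN_PAIRS:
                audit["skipped_small_n"].append((feat, out, n))
                continue
            x = pair[feat].to_numpy(dtype=float)
            y = pair[out].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                audit["undefined_rho"].append((feat, out))
                rows.append({"feature": feat, "outcome": out, "rho": np.nan,
                             "p_value": np.nan, "n": n, "defined": False})
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"feature": feat, "outcome": out, "rho": float(rho),
                         "p_value": float(p), "n": n, "defined": True})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["stars"] = table["p_value"].map(significance_stars)
    return table, audit


def significance_stars(p: float) -> str:
    """Per-cell threshold annotation: * .05, ** .01, *** .001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
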