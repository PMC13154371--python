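"""RT cleaning and within-person standardization.

Outlier handling uses an asymmetric IQR rule tuned to right-skewed RT
distributions: per item (pooled across subjects), trials outside
``[Q1 - 0.5*IQR, Q3 + 1.5*IQR]`` are excluded.  Quartiles use linear
interpolation between order statistics.  Bounds are computed once on the
raw data, then applied; both bounds are inclusive.

Standardized RTs (Z-RT) express each latency relative to the subject's
typical speed at the chosen Likert level:

    Z_ijk = (RT_ijk - mean_ij) / sigma_ij

per (subject i, item, option j) cell, with the population SD (ddof=0) so a
two-point cell standardizes to exactly ±1.  Cells with fewer than 2 trials
or zero SD cannot be standardized; they are dropped and counted in an audit
log rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("subject_id", "item", "day_index", "likert", "rt_seconds")


@dataclass(frozen=True)
class IqrBounds:
    """Asymmetric per-item exclusion bounds on raw RT (seconds)."""

    item: str
    q1: float
    q3: float
    lower: float
    upper: float


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")


def compute_iqr_bounds(records: pd.DataFrame) -> list[IqrBounds]:
    """Per-item asymmetric IQR bounds, quartiles pooled across subjects.

    Lower bound ``Q1 - 0.5*IQR``; upper bound ``Q3 + 1.5*IQR``.  Each item
    needs at least 4 trials for a meaningful quartile estimate.
    """
    _check_records(records)
    bounds = []
    for item, grp in records.groupby("item", sort=True):
        rt = grp["rt_seconds"].to_numpy(dtype=float)
        if rt.size < 4:
            raise ValueError(
                f"item {item!r} has only {rt.size} records (need >= 4)")
        q1, q3 = np.percentile(rt, [25, 75])  # linear interpolation
        iqr = q3 - q1
        bounds.append(IqrBounds(item=item, q1=float(q1), q3=float(q3),
                                lower=float(q1 - 0.5 * iqr),
                                upper=float(q3 + 1.5 * iqr)))
    return bounds


def filter_outliers(
    records: pd.DataFrame, bounds: list[IqrBounds],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (kept, removed) by the per-item bounds, inclusive."""
    _check_records(records)
    bmap = {b.item: b for b in bounds}
    missing = set(records["item"]) - set(bmap)
    if missing:
        raise ValueError(f"no bounds for items: {sorted(missing)}")
    if records.empty:
        return records.copy(), records.copy()
    lower = records["item"].map(lambda it: bmap[it].lower)
    upper = records["item"].map(lambda it: bmap[it].upper)
    keep = (records["rt_seconds"] >= lower) & (records["rt_seconds"] <= upper)
    return records[keep].copy(), records[~keep].copy()


def z_standardize(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Z-RT per (subject, item, option) cell with population-SD convention.

    Returns
    -------
    zrt : DataFrame
        Columns subject_id, item, option, day_index, z.  Only cells with
        n >= 2 and nonzero SD contribute.
    audit : dict
        Counts of dropped cells (``small_cells`` with n < 2,
        ``zero_sd_cells``) and of the records they contained.
    """
    _check_records(records)
    audit = {"small_cells": 0, "zero_sd_cells": 0, "dropped_records": 0,
             "cells": 0}
    parts = []
    for (sid, item, opt), grp in records.groupby(
            ["subject_id", "item", "likert"], sort=True):
        audit["cells"] += 1
        rt = grp["rt_seconds"].to_numpy(dtype=float)
        if rt.size < 2:
            audit["small_cells"] += 1
            audit["dropped_records"] += rt.size
            continue
        sd = rt.std(ddof=0)
        if sd == 0:
            audit["zero_sd_cells"] += 1
            audit["dropped_records"] += rt.size
            continue
        parts.append(pd.DataFrame({
            "subject_id": sid,
            "item": item,
            "option": opt,
            "day_index": grp["day_index"].to_numpy(),
            "z": (rt - rt.mean()) / sd,
        }))
    if parts:
        zrt = pd.concat(parts, ignore_index=True)
        zrt = zrt.sort_values(
            ["subject_id", "item", "option", "day_index"]
        ).reset_index(drop=True)
    else:
        zrt = pd.DataFrame(
            columns=["subject_id", "item", "option", "day_index", "z"])
    return zrt, audit


def cell_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, item, option) RT moments (population SD)."""
    _check_records(records)
    g = records.groupby(["subject_id", "item", "likert"], sort=True)
    out = g["rt_seconds"].agg(
        n="size", mean_rt="mean", sd_rt=lambda x: x.std(ddof=0))
    out.loc[out["n"] < 2, "sd_rt"] = np.nan
    return (out.reset_index()
            .rename(columns={"likert": "option"}))


def preprocess(records: pd.DataFrame) -> dict:
    """Full cleaning stage: bounds → filter → Z-RT, with an audit trail."""
    bounds = compute_iqr_bounds(records)
    kept, removed = filter_outliers(records, bounds)
    zrt, z_audit = z_standardize(kept)
    audit = {
        "bounds": [vars(b) for b in bounds],
        "n_input": int(len(records)),
        "n_kept": int(len(kept)),
        "n_removed": int(len(removed)),
        "z_cells": z_audit,
    }
    return {"kept": kept, "removed": removed, "zrt": zrt, "audit": audit}
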