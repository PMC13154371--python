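"""Per-subject EMA descriptive features and RT-adaptation (decay) fits.

Descriptives are the seven order/moment statistics (mean, SD, min, q25,
median, q75, max) of each subject × item series, computed for both the
Likert scores and the raw RTs.

Adaptation is summarized by a three-parameter exponential decay

    f(t) = theta_a * exp(-theta_b * t) + theta_c

fitted independently per subject (no partial pooling) by bounded nonlinear
least squares to the raw-RT and the standardized (Z-RT) series.  theta_a is
the initial elevation above the asymptote, theta_b the adaptation (decay)
rate, theta_c the stabilized post-adaptation level.  R² is
1 - SS_res/SS_tot, with R² defined as 0 for a constant series
(SS_tot = 0).  Bounded problems are solved with a trust-region reflective
least-squares method, since a pure Levenberg–Marquardt iteration cannot
honor bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

MAX_ITER = 10_000
STATS = ("mean", "sd", "min", "q25", "median", "q75", "max")


@dataclass(frozen=True)
class DecayFit:
    subject_id: str
    item: str
    source: str  # "raw_rt" | "z_rt"
    theta_a: float
    theta_b: float
    theta_c: float
    r_squared: float
    converged: bool
    n_points: int


def describe_series(records: pd.DataFrame) -> pd.DataFrame:
    """Seven descriptive statistics per (subject, item, source).

    ``source`` is "score" (the Likert answers) or "raw_rt" (latencies in
    seconds).  Quantiles use linear interpolation, matching the outlier
    rule's quartile convention.
    """
    rows = []
    for (sid, item), grp in records.groupby(["subject_id", "item"],
                                            sort=True):
        for source, col in (("score", "likert"), ("raw_rt", "rt_seconds")):
            x = grp[col].to_numpy(dtype=float)
            q25, med, q75 = np.percentile(x, [25, 50, 75])
            rows.append({
                "subject_id": sid, "item": item, "source": source,
                "mean": x.mean(), "sd": x.std(ddof=1) if x.size > 1 else 0.0,
                "min": x.min(), "q25": q25, "median": med, "q75": q75,
                "max": x.max(),
            })
    return pd.DataFrame(rows)


def _decay(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, b, c = params
    return a * np.exp(-b * t) + c


def fit_decay(t, y, source: str, subject_id: str = "", item: str = "",
              ) -> DecayFit | None:
    """Bounded NLS fit of ``y ≈ theta_a * exp(-theta_b * t) + theta_c``.

    Parameters
    ----------
    t, y : array-like
        Occasion indices (raw day index, or any monotone time axis the
        caller chooses) and the RT or Z-RT values.
    source : str
        "raw_rt" (parameters constrained nonnegative, scaled to the data
        range) or "z_rt" (amplitude and asymptote may be negative).

    Returns None when fewer than 4 finite points are available (the feature
    is reported as missing).  Non-convergence never raises: the last iterate
    is returned with ``converged=False``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    n = y.size
    if n < 4:
        return None

    order = np.argsort(t)
    t, y = t[order], y[order]
    q = max(1, n // 4)
    c0 = float(np.mean(y[-q:]))          # late-window level
    a0 = float(np.mean(y[:q]) - c0)      # early elevation above it
    b0 = 0.1

    if source == "raw_rt":
        ymax = max(float(y.max()), 1e-6)
        lb = np.array([0.0, 0.0, 0.0])
        ub = np.array([2.0 * ymax, 10.0, ymax])
    elif source == "z_rt":
        lb = np.array([-6.0, 0.0, -3.0])
        ub = np.array([6.0, 10.0, 3.0])
    else:
        raise ValueError(f"unknown source {source!r}")
    x0 = np.clip([a0, b0, c0], lb + 1e-9, ub - 1e-9)

    res = least_squares(
        lambda p: _decay(p, t) - y, x0, bounds=(lb, ub),
        method="trf", max_nfev=MAX_ITER)
    a, b, c = res.x
    ss_res = float(np.sum((_decay(res.x, t) - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DecayFit(subject_id=subject_id, item=item, source=source,
                    theta_a=float(a), theta_b=float(b), theta_c=float(c),
                    r_squared=r2, converged=bool(res.status > 0),
                    n_points=int(n))


def decay_fits(records: pd.DataFrame, zrt: pd.DataFrame) -> pd.DataFrame:
    """Per-subject decay fits for every item, on raw RT and on Z-RT.

    Time is the calendar day index (missed days leave gaps rather than
    re-indexing completed trials).
    """
    rows = []
    for (sid, item), grp in records.groupby(["subject_id", "item"],
                                            sort=True):
        fit = fit_decay(grp["day_index"], grp["rt_seconds"], "raw_rt",
                        subject_id=sid, item=item)
        if fit is not None:
            rows.append(vars(fit))
    for (sid, item), grp in zrt.groupby(["subject_id", "item"], sort=True):
        grp = grp.sort_values("day_index")
        fit = fit_decay(grp["day_index"], grp["z"], "z_rt",
                        subject_id=sid, item=item)
        if fit is not None:
            rows.append(vars(fit))
    return pd.DataFrame(rows)


def feature_table(descriptives: pd.DataFrame,
                  fits: pd.DataFrame) -> pd.DataFrame:
    """One wide row per subject: ``{item}_{source}_{stat}`` columns."""
    wide = {}
    for _, r in descriptives.iterrows():
        row = wide.setdefault(r["subject_id"], {})
        for stat in STATS:
            row[f"{r['item']}_{r['source']}_{stat}"] = r[stat]
    for _, r in fits.iterrows():
        row = wide.setdefault(r["subject_id"], {})
        base = f"{r['item']}_{r['source']}"
        row[f"{base}_theta_a"] = r["theta_a"]
        row[f"{base}_theta_b"] = r["theta_b"]
        row[f"{base}_theta_c"] = r["theta_c"]
        row[f"{base}_r2"] = r["r_squared"]
    out = pd.DataFrame.from_dict(wide, orient="index").sort_index()
    out.index.name = "subject_id"
    return out.reset_index()
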