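"""Synthetic EMA cohort generator.

Emulates a single-arm observational study in which ~49 older adults answer
four daily 7-point Likert items ("feeling", "appetite", "sleep_quality",
"general_evaluation") for ~28 days while their response times (RTs) are
logged, and complete a pre/post battery of symptom scales (GDS-15, CESD-R,
PHQ-9, BAI).

Generative model
----------------
For subject ``i`` in group ``g(i)`` (1 = responder), with normalized time
``t = day / (n_days - 1)``:

.. math::

    \\log \\theta_a(i) = \\beta_{0a} + \\beta_{1a} g(i) + \\sigma_a z_a(i)

    \\log \\theta_b(i) = \\beta_{0b} + \\beta_{1b} g(i) + \\sigma_b z_b(i)

    \\theta_c(i,r) = \\beta_{0c} + \\beta_{1c} g(i) + u_c(i)
                    + \\alpha_c(r) + \\epsilon_c(i,r)

    \\eta = \\theta_a(i) e^{-\\theta_b(i) t} + \\theta_c(i, r)

    RT \\sim \\mathrm{LogNormal}(\\eta, \\sigma_{\\log})

where ``r`` is the emitted Likert level (1..7).  Amplitude and decay rate
live on the log scale (positive by construction); the asymptote
:math:`\\theta_c` lives on the log-RT scale.  The defaults place the
responder/nonresponder ratio of the decay rate at 5 and of the
asymptotic RT at 1.25, a 6% missing-occasion rate (≈94% adherence), and
right-tail RT contamination by a multiplicative outlier process.

Likert responses come from a bounded AR(1) latent-mood process discretized
by fixed cutpoints; this is a stand-in coupling (the joint law of answer
content and latency in the real study is unknown) that produces a realistic
spread of option usage so option-level standardization is exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

ITEMS = ("feeling", "appetite", "sleep_quality", "general_evaluation")
N_OPTIONS = 7

# Pre-intervention scale distributions (mean, sd, max) for score batteries.
SCALE_RANGES = {"gds15": 15, "cesdr": 80, "phq9": 27, "bai": 63}
PRE_MOMENTS = {
    "gds15": (9.37, 4.42),
    "cesdr": (33.94, 18.24),
    "phq9": (13.04, 7.40),
    "bai": (22.76, 16.46),
}
MDC_GDS15 = -3.81

# Coupling of the other scales' change to the GDS-15 change (slope, noise sd).
_OTHER_DELTA = {"cesdr": (2.6, 8.0), "phq9": (1.3, 3.0), "bai": (1.6, 6.0)}


@dataclass
class SimConfig:
    """Generative truth for a synthetic EMA cohort.

    ``beta0_*`` are nonresponder centers (log scale for ``a``/``b``, log-RT
    scale for ``c``); ``beta1_*`` are additive responder effects on the same
    scales, so ``exp(beta1_b) = 5`` and ``exp(beta1_c) = 1.25`` reproduce the
    regime of interest.  ``gds_delta_sd`` controls the noise on the GDS-15
    change score around its group means (0 gives deterministic group
    separation around the MDC threshold).
    """

    n_subjects: int = 49
    n_days: int = 28
    items: Sequence[str] = ITEMS
    prop_responders: float = 0.30
    beta0_a: float = math.log(0.8)
    beta0_b: float = math.log(3.0)
    beta0_c: float = math.log(2.5)
    beta1_a: float = 0.0
    beta1_b: float = math.log(5.0)
    beta1_c: float = math.log(1.25)
    sigma_a: float = 0.30
    sigma_b: float = 0.40
    sigma_subj: float = 0.30
    sigma_cell: float = 0.10
    sigma_log: float = 0.30
    alpha_c: Sequence[float] = (-0.10, -0.02, 0.05, 0.14, 0.05, -0.02, -0.10)
    missing_rate: float = 0.06
    outlier_rate: float = 0.02
    outlier_scale: float = 8.0
    likert_coupling: float = 1.0
    gds_delta_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        vals = [
            self.beta0_a, self.beta0_b, self.beta0_c,
            self.beta1_a, self.beta1_b, self.beta1_c,
            self.sigma_a, self.sigma_b, self.sigma_subj, self.sigma_cell,
            self.sigma_log, self.prop_responders, self.missing_rate,
            self.outlier_rate, self.outlier_scale, self.likert_coupling,
            self.gds_delta_sd, *self.alpha_c,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("SimConfig contains non-finite values")
        for name in ("sigma_a", "sigma_b", "sigma_subj", "sigma_cell",
                     "sigma_log", "gds_delta_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("prop_responders", "missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_days < 3:
            raise ValueError("n_days must be >= 3")
        if len(self.alpha_c) != N_OPTIONS:
            raise ValueError(f"alpha_c must have length {N_OPTIONS}")
        if abs(sum(self.alpha_c)) > 1e-8:
            raise ValueError("alpha_c must sum to 0")
        n_resp = int(round(self.prop_responders * self.n_subjects))
        if n_resp == 0 or n_resp == self.n_subjects:
            raise ValueError(
                "prop_responders leaves one group empty "
                f"({n_resp}/{self.n_subjects} responders)"
            )


def _subject_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"s{i + 1:0{width}d}" for i in range(n)]


def _latent_likert(rng: np.random.Generator, cfg: SimConfig,
                   n_days: int) -> np.ndarray:
    """Likert levels for one subject: (n_days, n_items) integer array 1..7.

    Bounded AR(1) latent mood shared across the day's items, item-specific
    jitter, discretized by fixed cutpoints at ±0.5, ±1.5, ±2.5.
    """
    phi = 0.7
    x = np.empty(n_days)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n_days - 1) * math.sqrt(1 - phi ** 2)
    for d in range(1, n_days):
        x[d] = phi * x[d - 1] + innov[d - 1]
    mu = 0.5 * rng.standard_normal()
    lat = (mu + cfg.likert_coupling * x)[:, None] \
        + 0.5 * rng.standard_normal((n_days, len(cfg.items)))
    cut = np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])
    return np.searchsorted(cut, lat) + 1


def _truncated_round(rng: np.random.Generator, mean: float, sd: float,
                     size: int, low: float | None = None,
                     high: float | None = None) -> np.ndarray:
    """Rounded normal draws, redrawn until inside [low, high]."""
    out = np.round(rng.normal(mean, sd, size)) if sd > 0 \
        else np.full(size, round(mean), dtype=float)
    for _ in range(1000):
        bad = np.zeros(size, dtype=bool)
        if low is not None:
            bad |= out < low
        if high is not None:
            bad |= out > high
        if not bad.any():
            break
        n_bad = int(bad.sum())
        out[bad] = np.round(rng.normal(mean, sd, n_bad)) if sd > 0 \
            else round(mean)
        if sd == 0:  # nothing will change on redraw; clip instead
            out = np.clip(out, low if low is not None else -np.inf,
                          high if high is not None else np.inf)
            break
    else:
        out = np.clip(out, low if low is not None else -np.inf,
                      high if high is not None else np.inf)
    return out


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate one synthetic cohort.

    Returns
    -------
    records : DataFrame
        Long EMA records (subject_id, item, day_index, likert, rt_seconds),
        after missing-occasion dropout and outlier contamination.
    scales : DataFrame
        Pre/post batteries (subject_id, timepoint, gds15, cesdr, phq9, bai).
    truth : dict
        Generative truth: per-subject parameters and group labels
        (``truth["subjects"]``), the full asymptote matrix
        (``truth["theta_c"]``, subjects × options), option offsets and the
        config used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    S, D = config.n_subjects, config.n_days
    items = list(config.items)
    sids = _subject_ids(S)

    n_resp = int(round(config.prop_responders * S))
    g = np.zeros(S, dtype=int)
    g[rng.permutation(S)[:n_resp]] = 1

    theta_a = np.exp(config.beta0_a + config.beta1_a * g
                     + config.sigma_a * rng.standard_normal(S))
    theta_b = np.exp(config.beta0_b + config.beta1_b * g
                     + config.sigma_b * rng.standard_normal(S))
    u_c = config.sigma_subj * rng.standard_normal(S)
    eps_c = config.sigma_cell * rng.standard_normal((S, N_OPTIONS))
    alpha = np.asarray(config.alpha_c, dtype=float)
    theta_c = (config.beta0_c + config.beta1_c * g)[:, None] \
        + u_c[:, None] + alpha[None, :] + eps_c

    t_norm = np.arange(D) / (D - 1)
    rows = []
    for i, sid in enumerate(sids):
        likert = _latent_likert(rng, config, D)          # (D, n_items)
        decay = theta_a[i] * np.exp(-theta_b[i] * t_norm)  # (D,)
        eta = decay[:, None] + theta_c[i, likert - 1]
        rt = np.exp(eta + config.sigma_log
                    * rng.standard_normal((D, len(items))))
        out_mask = rng.random((D, len(items))) < config.outlier_rate
        rt = np.where(out_mask, rt * config.outlier_scale, rt)
        keep_day = rng.random(D) >= config.missing_rate
        for d in range(D):
            if not keep_day[d]:
                continue
            for j, item in enumerate(items):
                rows.append((sid, item, d, int(likert[d, j]),
                             float(rt[d, j])))
    records = pd.DataFrame(
        rows, columns=["subject_id", "item", "day_index", "likert",
                       "rt_seconds"])

    scales = _generate_scales(rng, config, sids, g)

    truth_subjects = pd.DataFrame({
        "subject_id": sids,
        "is_responder": g,
        "theta_a": theta_a,
        "theta_b": theta_b,
        "u_c": u_c,
    })
    theta_c_df = pd.DataFrame(
        theta_c, index=pd.Index(sids, name="subject_id"),
        columns=[f"option_{r}" for r in range(1, N_OPTIONS + 1)])
    truth = {
        "subjects": truth_subjects,
        "theta_c": theta_c_df,
        "alpha_c": alpha.tolist(),
        "config": asdict(config),
    }
    truth["config"]["items"] = items
    truth["config"]["alpha_c"] = alpha.tolist()
    return records, scales, truth


def _generate_scales(rng: np.random.Generator, cfg: SimConfig,
                     sids: list[str], g: np.ndarray) -> pd.DataFrame:
    """Pre/post batteries with GDS-15 change respecting the MDC threshold.

    Responders receive an integer GDS-15 drop of at least 4 points
    (Δ ≤ −3.81 on the integer scale), nonresponders a change above the
    threshold; ``gds_delta_sd`` perturbs the group means.  Pre scores are
    raised where needed so a responder's drop fits inside [0, 15].
    """
    S = len(sids)
    pre = {}
    for scale, (m, sd) in PRE_MOMENTS.items():
        pre[scale] = _truncated_round(rng, m, sd, S, 0, SCALE_RANGES[scale])

    d_gds = np.where(
        g == 1,
        _truncated_round(rng, -6.0, cfg.gds_delta_sd, S, high=-4),
        _truncated_round(rng, -0.8, cfg.gds_delta_sd, S, low=-3),
    )
    pre["gds15"] = np.maximum(pre["gds15"], -d_gds)
    post = {"gds15": np.clip(pre["gds15"] + d_gds, 0, 15)}
    for scale, (slope, noise) in _OTHER_DELTA.items():
        d = np.round(slope * d_gds + rng.normal(0, noise, S))
        post[scale] = np.clip(pre[scale] + d, 0, SCALE_RANGES[scale])

    recs = []
    for tp, table in (("pre", pre), ("post", post)):
        for i, sid in enumerate(sids):
            recs.append((sid, tp, int(table["gds15"][i]),
                         int(table["cesdr"][i]), int(table["phq9"][i]),
                         int(table["bai"][i])))
    return pd.DataFrame(
        recs, columns=["subject_id", "timepoint", "gds15", "cesdr",
                       "phq9", "bai"])


def write_cohort(outdir, records: pd.DataFrame, scales: pd.DataFrame,
                 truth: dict) -> dict:
    """Write ema_records.csv, scales.csv and truth.json; return the paths."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "ema_records.csv",
        "scales": outdir / "scales.csv",
        "truth": outdir / "truth.json",
    }
    records.to_csv(paths["records"], index=False)
    scales.to_csv(paths["scales"], index=False)
    payload = {
        "subjects": truth["subjects"].to_dict(orient="list"),
        "theta_c": truth["theta_c"].reset_index().to_dict(orient="list"),
        "alpha_c": truth["alpha_c"],
        "config": truth["config"],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
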