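"""Stage orchestration: simulate → preprocess → features → outcomes →
associate → model, as a configurable, logged, reproducible run.

Each stage reads the previous stage's CSV/JSON artifacts from the run
directory and writes its own, so partial reruns can reuse cached upstream
outputs.  A single global seed is forked deterministically into per-stage
seeds; the run manifest records stage statuses, artifact paths, seeds,
package versions and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ema_rt import association, features, hierarchical, outcomes, preprocess
from ema_rt.simulate import SimConfig, generate_cohort, write_cohort

log = logging.getLogger("ema_rt")

STAGES = ("simulate", "preprocess", "features", "outcomes", "associate",
          "model")

RECORD_DTYPES = {"subject_id": str, "item": str, "day_index": int,
                 "likert": int, "rt_seconds": float}


@dataclass
class RunConfig:
    """One pipeline run.

    Either ``simulate=True`` (with ``sim`` as the generative truth) or
    ``records_path``/``scales_path`` pointing at existing CSVs.
    """

    outdir: str = "results/run"
    seed: int = 0
    stages: tuple = STAGES
    simulate: bool = True
    sim: SimConfig | None = None
    records_path: str | None = None
    scales_path: str | None = None
    item: str = "feeling"
    variant: str = "b_and_c"
    moderated: bool = True
    loo_variants: tuple = ("none", "b_and_c")
    run_sensitivity: bool = False
    make_plots: bool = True
    mcmc: hierarchical.McmcConfig = field(
        default_factory=hierarchical.McmcConfig)

    def validate(self):
        if not self.simulate and not (self.records_path and self.scales_path):
            raise ValueError(
                "provide input paths or set simulate=True, not neither")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _stage_seed(global_seed: int, stage: str) -> int:
    h = np.random.SeedSequence([global_seed, STAGES.index(stage)])
    return int(h.generate_state(1)[0] % (2 ** 31))


def _config_hash(config: RunConfig) -> str:
    payload = asdict(config)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def read_records(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=RECORD_DTYPES)
    except (ValueError, TypeError) as err:
        raise ValueError(f"malformed records CSV {path}: {err}") from err
    missing = set(RECORD_DTYPES) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_scales(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "timepoint": str})
    need = {"subject_id", "timepoint", "gds15", "cesdr", "phq9", "bai"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def run(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
        "artifacts": {},
    }
    halted = False
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if halted:
            manifest["stages"][stage] = {"status": "skipped_upstream_failure"}
            continue
        t0 = time.time()
        try:
            arts = _STAGE_FUNCS[stage](config, outdir)
            manifest["stages"][stage] = {
                "status": "ok",
                "seed": _stage_seed(config.seed, stage),
                "seconds": round(time.time() - t0, 2),
            }
            manifest["artifacts"].update(arts)
            log.info("stage %s ok (%.1fs)", stage, time.time() - t0)
        except Exception as err:  # halt downstream, keep the record
            manifest["stages"][stage] = {"status": "failed",
                                         "error": str(err)}
            log.error("stage %s failed: %s", stage, err)
            halted = True
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    manifest["artifacts"]["manifest"] = str(outdir / "manifest.json")
    return manifest


def _versions() -> dict:
    import arviz
    import scipy

    import ema_rt
    return {"ema_rt": ema_rt.__version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "arviz": arviz.__version__}


# ----------------------------------------------------------------- stages
def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    if not config.simulate:
        return {"records": config.records_path,
                "scales": config.scales_path}
    sim = config.sim or SimConfig()
    sim = SimConfig(**{**asdict(sim),
                       "seed": _stage_seed(config.seed, "simulate")})
    records, scales, truth = generate_cohort(sim)
    log.info("simulated %d records, %d subjects", len(records),
             sim.n_subjects)
    return write_cohort(outdir, records, scales, truth)


def _records_in(config: RunConfig, outdir: Path) -> pd.DataFrame:
    path = config.records_path if not config.simulate \
        else outdir / "ema_records.csv"
    return read_records(path)


def _stage_preprocess(config: RunConfig, outdir: Path) -> dict:
    records = _records_in(config, outdir)
    result = preprocess.preprocess(records)
    kept_path = outdir / "ema_records_clean.csv"
    zrt_path = outdir / "zrt.csv"
    audit_path = outdir / "preprocess_audit.json"
    result["kept"].to_csv(kept_path, index=False)
    result["zrt"].to_csv(zrt_path, index=False)
    with open(audit_path, "w") as fh:
        json.dump(result["audit"], fh, indent=1)
    log.info("preprocess: %d in, %d kept, %d removed",
             result["audit"]["n_input"], result["audit"]["n_kept"],
             result["audit"]["n_removed"])
    return {"records_clean": str(kept_path), "zrt": str(zrt_path),
            "preprocess_audit": str(audit_path)}


def _stage_features(config: RunConfig, outdir: Path) -> dict:
    kept = read_records(outdir / "ema_records_clean.csv")
    zrt = pd.read_csv(outdir / "zrt.csv", dtype={"subject_id": str})
    desc = features.describe_series(kept)
    fits = features.decay_fits(kept, zrt)
    table = features.feature_table(desc, fits)
    path = outdir / "features.csv"
    table.to_csv(path, index=False)
    log.info("features: %d subjects x %d columns", len(table),
             table.shape[1] - 1)
    return {"features": str(path)}


def _stage_outcomes(config: RunConfig, outdir: Path) -> dict:
    scales = read_scales(config.scales_path if not config.simulate
                         else outdir / "scales.csv")
    changes, audit = outcomes.change_scores(scales)
    labels = outcomes.classify_responder(changes)
    table = changes.merge(labels, on="subject_id")
    path = outdir / "outcomes.csv"
    table.to_csv(path, index=False)
    tests = outcomes.paired_test_suite(scales)
    tests_path = outdir / "paired_tests.json"
    with open(tests_path, "w") as fh:
        json.dump({t.scale: asdict(t) for t in tests}, fh, indent=1,
                  default=float)
    log.info("outcomes: %d subjects, %d responders; %s",
             len(table), int(table["is_responder"].sum()), audit)
    return {"outcomes": str(path), "paired_tests": str(tests_path)}


def _stage_associate(config: RunConfig, outdir: Path) -> dict:
    feats = pd.read_csv(outdir / "features.csv", dtype={"subject_id": str})
    changes = pd.read_csv(outdir / "outcomes.csv", dtype={"subject_id": str})
    table, audit = association.correlation_matrix(feats, changes)
    path = outdir / "correlations.csv"
    table.to_csv(path, index=False)
    log.info("associations: %d cells, %d undefined", len(table),
             len(audit["undefined_rho"]))
    return {"correlations": str(path)}


def _stage_model(config: RunConfig, outdir: Path) -> dict:
    kept = read_records(outdir / "ema_records_clean.csv")
    table = pd.read_csv(outdir / "outcomes.csv", dtype={"subject_id": str})
    labels = table[["subject_id", "is_responder"]]
    if config.item == "average":
        item_records = hierarchical.averaged_outcome(kept)
    else:
        item_records = kept[kept["item"] == config.item]
    seed = _stage_seed(config.seed, "model")
    mc = hierarchical.McmcConfig(
        **{**asdict(config.mcmc), "seed": seed})

    # nested variant comparison without moderation
    loo_fits = []
    for variant in config.loo_variants:
        spec = hierarchical.HierarchicalSpec(
            variant=variant, moderated=False, mcmc=mc)
        loo_fits.append(
            (variant, hierarchical.fit(item_records, labels, spec)))
    loo = hierarchical.compare_loo(loo_fits)
    loo_path = outdir / "loo_comparison.csv"
    loo.to_csv(loo_path, index=False)
    selected = config.variant or loo.iloc[0]["variant"]
    log.info("LOO ranking:\n%s\nselected variant: %s", loo, selected)

    # moderated fit on the selected structure
    spec = hierarchical.HierarchicalSpec(
        variant=selected, moderated=config.moderated, mcmc=mc)
    post = hierarchical.fit(item_records, labels, spec)
    effects = []
    if config.moderated:
        for par in ("theta_b", "exp_theta_c", "theta_a"):
            effects.append(asdict(hierarchical.group_effect_summary(post,
                                                                    par)))
    eff_path = outdir / "group_effects.csv"
    pd.DataFrame(effects).to_csv(eff_path, index=False)

    ppc = hierarchical.ppc_binned(post, n_bins=10, seed=seed)
    ppc_path = outdir / "ppc.csv"
    ppc.to_csv(ppc_path, index=False)

    diag = {
        "rhat_max": post.rhat_max,
        "ess_min": post.ess_min,
        "divergence_frac": post.divergence_frac,
        "reliable": post.reliable,
        "warnings": post.warnings,
        "ppc_coverage": float(ppc["covered"].mean()),
        "n_obs": post.model.n_obs,
        "n_subjects": post.model.n_sub,
        "excluded_small_subjects":
            post.model.audit["excluded_small_subjects"],
    }
    diag_path = outdir / "diagnostics.json"
    with open(diag_path, "w") as fh:
        json.dump(diag, fh, indent=1)

    arts = {"loo_comparison": str(loo_path), "group_effects": str(eff_path),
            "ppc": str(ppc_path), "diagnostics": str(diag_path)}
    if config.make_plots:
        arts.update(_model_plots(post, ppc, outdir))
    if config.run_sensitivity:
        sens = hierarchical.sensitivity_suite(item_records, labels, spec)
        sens_path = outdir / "sensitivity.csv"
        sens.to_csv(sens_path, index=False)
        arts["sensitivity"] = str(sens_path)
    return arts


def _model_plots(post, ppc: pd.DataFrame, outdir: Path) -> dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(ppc["t_mid"], ppc["interval_low"], ppc["interval_high"],
                    alpha=0.3, label="94% predictive interval")
    ax.plot(ppc["t_mid"], ppc["predictive_median"], label="predictive median")
    ax.plot(ppc["t_mid"], ppc["observed_mean_rt"], "o-",
            label="observed bin mean")
    ax.set_xlabel("normalized time")
    ax.set_ylabel("RT (s)")
    ax.legend()
    ppc_png = outdir / "ppc_plot.png"
    fig.tight_layout()
    fig.savefig(ppc_png, dpi=100)
    plt.close(fig)

    trace_png = outdir / "trace_plot.png"
    names = [n for n in ("beta1_b", "beta1_c", "beta0_b", "sigma_log")
             if n in post.model.slices
             or n.replace("sigma_", "s_") in post.model.slices]
    fig, axes = plt.subplots(len(names), 1, figsize=(6, 2 * len(names)),
                             squeeze=False)
    for k, name in enumerate(names):
        slot = post.model.slices.get(name) \
            or post.model.slices[name.replace("sigma_", "s_")]
        for c in range(post.draws.shape[0]):
            axes[k, 0].plot(post.draws[c, :, slot.start], lw=0.5)
        axes[k, 0].set_ylabel(name)
    fig.tight_layout()
    fig.savefig(trace_png, dpi=100)
    plt.close(fig)
    return {"ppc_plot": str(ppc_png), "trace_plot": str(trace_png)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "features": _stage_features,
    "outcomes": _stage_outcomes,
    "associate": _stage_associate,
    "model": _stage_model,
}
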