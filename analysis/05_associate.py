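"""Spearman screen of EMA features against symptom-change scores.

Correlates every feature column with the four change scores and reports
the strongest GDS-15 associations, including the Z-RT decay-rate cell
that is the analysis's key signal.
"""

import argparse
import logging

import pandas as pd

from ema_rt.pipeline import RunConfig, run

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/pipeline")
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    manifest = run(RunConfig(outdir=args.outdir, seed=args.seed,
                             stages=("associate",)))
    table = pd.read_csv(manifest["artifacts"]["correlations"])
    gds = table[(table["outcome"] == "d_gds15") & table["defined"]]
    top = gds.reindex(gds["rho"].abs().sort_values(ascending=False).index)
    print("strongest GDS-15 change associations:")
    print(top.head(8)[["feature", "rho", "p_value", "stars"]]
          .to_string(index=False))
    key = gds[gds["feature"] == "feeling_z_rt_theta_b"]
    if not key.empty:
        row = key.iloc[0]
        print(f"\nfeeling Z-RT decay rate vs d_gds15: rho={row['rho']:.3f} "
              f"(negative rho = faster adaptation, larger improvement)")
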