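"""Risk of Non-Adaptedness under SSP126 and SSP585 for the synthetic cohort.

Prunes mutually correlated environmental variables (|r| > 0.8), fits the
per-SNP allele-frequency ~ environment lines for the GEA candidates, and
projects the r^2-weighted mean required allele-frequency shift per
population and scenario.  Writes results/rona/.
"""

from pathlib import Path

import pandas as pd

from islandadapt import (
    EnvPruneConfig,
    RonaConfig,
    compute_rona,
    fit_freq_env,
    prune_env,
)
from islandadapt.io_formats import read_env_table, read_pop_map, read_vcf

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "rona"
    out.mkdir(parents=True, exist_ok=True)

    pop_map = read_pop_map(ROOT / "cohort" / "popmap.tsv")
    g = read_vcf(ROOT / "filtered" / "filtered.vcf", pop_map=pop_map)
    env = read_env_table(
        ROOT / "cohort" / "env.current.csv",
        {"SSP126": ROOT / "cohort" / "env.SSP126.csv",
         "SSP585": ROOT / "cohort" / "env.SSP585.csv"},
    )
    retained, dropped = prune_env(env, EnvPruneConfig())
    if dropped:
        for d, k, r in dropped:
            print(f"dropped {d} (|r| = {abs(r):.2f} with {k})")
    env = env.subset_variables(retained)

    cand = pd.read_csv(ROOT / "gea" / "candidates.tsv", sep="\t")
    by_var = {
        v: sub["snp_index"].to_numpy()
        for v, sub in cand.groupby("variable", sort=False)
        if v in retained
    }
    cfg = RonaConfig()
    models = fit_freq_env(g, env, by_var, cfg)
    frames = []
    for scen in ("SSP126", "SSP585"):
        frames.append(compute_rona(models, env, scen, cfg).summary)
    summary = pd.concat(frames, ignore_index=True)
    summary.to_csv(out / "rona.tsv", sep="\t", index=False)
    models.to_csv(out / "models.tsv", sep="\t", index=False)

    print(f"variables retained after pruning: {', '.join(retained)}")
    print(f"per-SNP models fitted: {len(models)} (mean r2 = {models['r2'].mean():.3f})")
    for scen in ("SSP126", "SSP585"):
        sub = summary[summary["scenario"] == scen]
        pv = sub.groupby("population")["rona"].mean()
        print(f"{scen}: mean RONA {sub['rona'].mean():.3f}; "
              "per population "
              + ", ".join(f"{p}={v:.3f}" for p, v in pv.items()))


if __name__ == "__main__":
    main()
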