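"""Simulation benchmarks tying the pipeline stages to generator ground truth.

Each function sets up the synthetic study conditions for one stage, runs the
stage, and scores it against the generator's truth: sweep localization
against the true selected site, GEA power/FDR against planted loci, the
structure generator against a Weir-Cockerham F_ST oracle, the sweep
simulator against Watterson's theta, and RONA against analytic cases.
The same routines back the test suite, the acceptance script and the
analysis drivers, so every report recomputes its numbers from scratch.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .gea import GeaConfig, candidate_union, fit_association
from .io_formats import GenotypeMatrix
from .rona import RonaConfig, compute_rona, fit_freq_env
from .sweep import SweepConfig, mu_scan
from .synth import (
    GeaSimConfig,
    StructureSimConfig,
    SweepSimConfig,
    inject_env_association,
    sim_env,
    sim_structured_genotypes,
    sim_sweep,
)

#: Scan window for the desk-scaled sweep benchmark: a 100-SNP window spans
#: roughly the expected sweep footprint (~15-30 kb at the generator's
#: default rates), which localizes the arg-max better than sub-footprint
#: windows.
BENCH_SCAN_WINDOW: int = 100


def sweep_localization(
    n_reps: int = 20,
    seed: int = 0,
    sim: SweepSimConfig | None = None,
    scan: SweepConfig | None = None,
) -> dict:
    """Hard-sweep localization: fraction of replicates whose arg-max mu
    window center lies within 25 kb of the true selected site."""
    base = sim or SweepSimConfig()
    cfg = scan or SweepConfig(window_snps=BENCH_SCAN_WINDOW)
    errors = []
    for r in range(n_reps):
        g, true_pos = sim_sweep(replace(base, seed=seed + 7919 * r))
        windows = mu_scan(g, cfg).windows
        best = windows.loc[windows["mu"].idxmax()]
        errors.append(abs(float(best["center"]) - true_pos))
    errors = np.asarray(errors)
    return {
        "hit_rate_25kb": float((errors <= 25_000).mean()),
        "median_error_kb": float(np.median(errors) / 1000),
        "n_reps": n_reps,
    }


def neutral_scan_exceedance(
    seed: int = 0, sim: SweepSimConfig | None = None, scan: SweepConfig | None = None
) -> dict:
    """Neutral control: fraction of windows above the genome-wide top-
    quantile threshold (definitionally ~ the top quantile itself)."""
    base = sim or SweepSimConfig()
    cfg = scan or SweepConfig(window_snps=BENCH_SCAN_WINDOW)
    g, _ = sim_sweep(replace(base, s=0.0, seed=seed))
    result = mu_scan(g, cfg)
    frac = float((result.windows["mu"] >= result.threshold).mean())
    return {"exceed_frac": frac, "top_quantile": cfg.top_quantile,
            "n_windows": int(len(result.windows))}


def gea_recovery(
    n_seeds: int = 10,
    seed: int = 0,
    n_per_pop: int = 60,
    n_snps: int = 10_000,
    n_adaptive: int = 100,
    fst: float = 0.1,
    latent_rank: int = 2,
    K_fit: int = 2,
    fdr_threshold: float = 0.01,
) -> dict:
    """Power and empirical FDR of the latent-factor GEA against planted
    loci, averaged over simulation seeds.  Structure is rank-``latent_rank``
    so the factor model can absorb it; the fit uses ``K_fit`` factors."""
    powers, fdrs = [], []
    for r in range(n_seeds):
        s = seed + 104729 * r
        g = sim_structured_genotypes(
            StructureSimConfig(
                n_pops=5, n_per_pop=n_per_pop, n_snps=n_snps, fst=fst,
                latent_rank=latent_rank, seed=s,
            )
        )
        gcfg = GeaSimConfig(n_adaptive_loci=n_adaptive, seed=s)
        env = sim_env(gcfg, 5)
        g, truth = inject_env_association(g, env, gcfg)
        res = fit_association(
            g, env, cfg=GeaConfig(K=K_fit, fdr_threshold=fdr_threshold)
        )
        union, _ = candidate_union(res)
        planted = set(int(i) for i in truth["snp_index"])
        found = set(int(i) for i in union)
        tp = len(planted & found)
        fp = len(found - planted)
        powers.append(tp / n_adaptive)
        fdrs.append(fp / max(len(found), 1))
    return {
        "mean_power": float(np.mean(powers)),
        "mean_fdr": float(np.mean(fdrs)),
        "n_seeds": n_seeds,
    }


def gea_null_uniformity(
    seed: int = 0, n_snps: int = 10_000, n_per_pop: int = 12
) -> dict:
    """KS distance of calibrated p-values from uniform on null data where
    the environment is independent of everything."""
    g = sim_structured_genotypes(
        StructureSimConfig(
            n_pops=5, n_per_pop=n_per_pop, n_snps=n_snps, fst=1e-4, seed=seed
        )
    )
    gcfg = GeaSimConfig(n_adaptive_loci=0, variables=("E1",), seed=seed)
    env = sim_env(gcfg, 5)
    res = fit_association(g, env, cfg=GeaConfig(K=2))
    p = res.table["p_cal"].to_numpy()
    return {"ks_stat": float(stats.kstest(p, "uniform").statistic), "n_snps": n_snps}


def fst_recovery(fst: float = 0.1, seed: int = 0, n_snps: int = 20_000) -> dict:
    """Weir-Cockerham F_ST of a Balding-Nichols simulation vs its target."""
    g = sim_structured_genotypes(
        StructureSimConfig(n_pops=5, n_per_pop=20, n_snps=n_snps, fst=fst, seed=seed)
    )
    return {
        "target": fst,
        "estimate": float(weir_cockerham_fst(g)),
        "n_snps": n_snps,
    }


def watterson_check(
    n_reps: int = 8,
    seed: int = 0,
    n_diploid: int = 100,
    seq_len: int = 50_000,
    mu: float = 1e-6,
    n_sample: int = 50,
) -> dict:
    """Mean segregating-site count in neutral runs vs Watterson's
    expectation 4*N*mu*L*a_{n-1} at the sampled size."""
    counts = []
    for r in range(n_reps):
        g, _ = sim_sweep(
            SweepSimConfig(
                n_diploid=n_diploid, seq_len=seq_len, mu=mu, s=0.0,
                n_sample=n_sample, seed=seed + 15485863 * r,
            )
        )
        counts.append(g.n_snps)
    a = float(sum(1.0 / i for i in range(1, n_sample)))
    expected = 4 * n_diploid * mu * seq_len * a
    return {
        "mean_segregating_sites": float(np.mean(counts)),
        "watterson_expectation": expected,
        "ratio": float(np.mean(counts) / expected),
        "n_reps": n_reps,
    }


def rona_pipeline_summary(seed: int = 0, n_snps: int = 4000, n_adaptive: int = 80) -> dict:
    """End-to-end GEA -> RONA on one synthetic dataset; returns the mean
    RONA per scenario and the mean per-SNP r^2 over used models."""
    g = sim_structured_genotypes(
        StructureSimConfig(
            n_pops=5, n_per_pop=20, n_snps=n_snps, fst=0.1, latent_rank=2,
            seed=seed,
        )
    )
    gcfg = GeaSimConfig(n_adaptive_loci=n_adaptive, seed=seed)
    env = sim_env(gcfg, 5)
    g, truth = inject_env_association(g, env, gcfg)
    res = fit_association(g, env, cfg=GeaConfig(K=2, fdr_threshold=0.01))
    cand = res.table[res.table["candidate"]]
    by_var = {
        v: sub["snp_index"].to_numpy()
        for v, sub in cand.groupby("variable", sort=False)
    }
    cfg = RonaConfig()
    out: dict = {"n_candidates": int(cand["snp_index"].nunique())}
    if not by_var:
        return out
    models = fit_freq_env(g, env, by_var, cfg)
    out["mean_r2"] = float(models["r2"].mean())
    for scen in ("SSP126", "SSP585"):
        rep = compute_rona(models, env, scen, cfg)
        out[f"mean_rona_{scen.lower()}"] = float(np.nanmean(rep.summary["rona"]))
    return out


def weir_cockerham_fst(g: GenotypeMatrix) -> float:
    """Weir-Cockerham theta (ratio of sums over loci) from the standard
    variance-components formulas."""
    pops = g.populations
    rows = {p: g.samples_of_pop(p) for p in pops}
    A = B = C = 0.0
    dos = g.dosages
    for j in range(g.n_snps):
        n_i, p_i, h_i = [], [], []
        for p in pops:
            d = dos[rows[p], j]
            d = d[d >= 0]
            if len(d) == 0:
                continue
            n_i.append(len(d))
            p_i.append(d.sum() / (2.0 * len(d)))
            h_i.append(float((d == 1).mean()))
        if len(n_i) < 2:
            continue
        n_i = np.asarray(n_i, float)
        p_i = np.asarray(p_i)
        h_i = np.asarray(h_i)
        r = len(n_i)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        if nc == 0:
            continue
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        A += a
        B += b
        C += c
    return A / (A + B + C)
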