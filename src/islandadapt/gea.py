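"""Latent-factor-corrected genotype-environment association (GEA).

Population structure is absorbed by K latent factors estimated from the
genotype matrix (truncated SVD of the column-centered, mean-imputed dosage
matrix, the standard PCA surrogate for latent-factor mixed models).  Each
environmental variable is then tested per SNP by least squares of dosage on
[1, environment, factors]; z-scores are recalibrated with the genomic
inflation factor lambda = median(z^2) / median(chi^2_1) before q-value FDR
control.  SNPs with q below the FDR threshold (default 1%) are candidates;
their genomic clustering is summarized in non-overlapping 1-Mb windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .io_formats import MISSING, EnvTable, GenotypeMatrix

_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class GeaConfig:
    K: int = 4
    fdr_threshold: float = 0.01
    hotspot_window: int = 1_000_000
    calibrate: bool = True
    #: q-values and the FDR rule are applied per variable by default;
    #: pooling ranks all (SNP, variable) p-values in one batch instead.
    pool_qvalues: bool = False

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must be in (0, 1)")


@dataclass
class GeaResult:
    """Association results, long format: one row per (SNP, variable)."""

    table: pd.DataFrame  # variable, snp_index, chrom, pos, effect, z, p_raw, p_cal, q, candidate
    inflation: dict[str, float]
    U: np.ndarray
    fdr_threshold: float

    def for_variable(self, variable: str) -> pd.DataFrame:
        return self.table[self.table["variable"] == variable]

    def candidate_counts(self) -> dict[str, int]:
        return {
            v: int(sub["candidate"].sum())
            for v, sub in self.table.groupby("variable", sort=False)
        }


def impute_dosages(g: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with missing calls replaced by the SNP mean."""
    x = g.dosages.astype(float)
    miss = g.dosages == MISSING
    if miss.any():
        obs = ~miss
        with np.errstate(invalid="ignore"):
            mean = np.where(obs, x, 0.0).sum(axis=0) / obs.sum(axis=0)
        mean = np.nan_to_num(mean)
        x = np.where(miss, mean[None, :], x)
    return x


def estimate_latent_factors(g: GenotypeMatrix, K: int) -> np.ndarray:
    """Top-K left singular vectors of the centered dosage matrix, scaled by
    their singular values; column signs fixed so the largest-magnitude
    entry of each column is positive."""
    if K == 0:
        return np.empty((g.n_samples, 0))
    if K >= g.n_samples:
        raise ValueError(f"K = {K} must be < n_samples = {g.n_samples}")
    x = impute_dosages(g)
    x = x - x.mean(axis=0)
    u, sing, _ = np.linalg.svd(x, full_matrices=False)
    U = u[:, :K] * sing[:K]
    for k in range(K):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    return U


def qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoother-estimated pi0.

    pi0 is estimated on the grid lambda = 0.05, 0.10, ..., 0.95 with a
    cubic smoothing spline evaluated at the largest lambda.  For fewer than
    100 p-values the Benjamini–Hochberg fallback (pi0 = 1) is used.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi0_lam = np.array([(p > la).mean() / (1.0 - la) for la in lam])
            spline = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(np.clip(spline(lam[-1]), 1.0 / m, 1.0))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fit_association(
    g: GenotypeMatrix,
    env: EnvTable,
    U: np.ndarray | None = None,
    cfg: GeaConfig | None = None,
) -> GeaResult:
    """Per-SNP, per-variable least-squares association with latent-factor
    correction and genomic-inflation calibration.

    Environment values are population-level constants expanded to samples.
    Each variable is tested in its own model; q-values and the candidate
    rule (q < fdr_threshold) are applied per variable.
    """
    cfg = cfg or GeaConfig()
    if U is None:
        U = estimate_latent_factors(g, cfg.K)
    K = U.shape[1]
    n = g.n_samples
    df = n - K - 2
    if df < 1:
        raise ValueError(f"too few samples (n={n}) for K={K} factors")
    y = impute_dosages(g)
    y_sd = y.std(axis=0)
    env_samples = env.expand_to_samples(g.pop_of_sample, "current")

    frames = []
    inflation: dict[str, float] = {}
    for v in env.variables:
        e = env_samples[v].to_numpy(dtype=float)
        if e.std() == 0.0:
            raise ValueError(f"environmental variable {v!r} is constant")
        e_std = (e - e.mean()) / e.std()
        X = np.column_stack([np.ones(n), e_std, U])
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ (X.T @ y)               # (K+2, S)
        resid = y - X @ beta
        rss = (resid**2).sum(axis=0)
        sigma2 = rss / df
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta[1] / se
        degenerate = (y_sd == 0.0) | (se == 0.0)
        z = np.where(degenerate, 0.0, z)
        p_raw = 2.0 * stats.t.sf(np.abs(z), df)
        p_raw = np.where(degenerate, 1.0, p_raw)
        if cfg.calibrate:
            lam = float(np.median(z**2) / _CHI2_MEDIAN)
            lam = max(lam, 1e-12)
            p_cal = stats.chi2.sf(z**2 / lam, df=1)
            p_cal = np.where(degenerate, 1.0, p_cal)
        else:
            lam = 1.0
            p_cal = p_raw
        q = qvalues(p_cal) if not cfg.pool_qvalues else np.full_like(p_cal, np.nan)
        inflation[v] = lam
        frames.append(
            pd.DataFrame(
                {
                    "variable": v,
                    "snp_index": np.arange(g.n_snps),
                    "chrom": g.chrom,
                    "pos": g.pos,
                    "effect": beta[1],
                    "z": z,
                    "p_raw": p_raw,
                    "p_cal": p_cal,
                    "q": q,
                    "candidate": q < cfg.fdr_threshold,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if cfg.pool_qvalues:
        q = qvalues(table["p_cal"].to_numpy())
        table["q"] = q
        table["candidate"] = q < cfg.fdr_threshold
    return GeaResult(
        table=table,
        inflation=inflation,
        U=U,
        fdr_threshold=cfg.fdr_threshold,
    )


def candidate_union(result: GeaResult) -> tuple[np.ndarray, dict[str, int]]:
    """SNP indices significant for at least one variable, plus per-variable
    counts (one SNP may count toward several variables)."""
    cand = result.table[result.table["candidate"]]
    union = np.unique(cand["snp_index"].to_numpy())
    return union, result.candidate_counts()


def hotspot_windows(
    candidate_idx: np.ndarray, g: GenotypeMatrix, window: int = 1_000_000
) -> tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """Bin candidate SNPs into non-overlapping windows per chromosome.

    Returns (per-window counts, per-chromosome totals, Pearson r between
    chromosome span and candidate count, its p-value).
    """
    candidate_idx = np.asarray(candidate_idx)
    rows = []
    chrom_rows = []
    for c in dict.fromkeys(g.chrom):
        on = g.chrom == c
        span = int(g.pos[on].max())
        in_c = candidate_idx[np.isin(candidate_idx, np.flatnonzero(on))]
        pos = g.pos[in_c]
        n_win = span // window + 1
        counts = np.bincount((pos - 1) // window, minlength=n_win)
        for w in range(n_win):
            rows.append((c, w * window, (w + 1) * window, int(counts[w])))
        chrom_rows.append((c, span, int(len(in_c))))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    per_chrom = pd.DataFrame(chrom_rows, columns=["chrom", "span_bp", "count"])
    if len(per_chrom) > 2 and per_chrom["count"].std() > 0 and per_chrom["span_bp"].std() > 0:
        r, pval = stats.pearsonr(per_chrom["span_bp"], per_chrom["count"])
    else:
        r, pval = np.nan, np.nan
    return windows, per_chrom, float(r), float(pval)
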