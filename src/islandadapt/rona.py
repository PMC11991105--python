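"""Risk of Non-Adaptedness (RONA) under future climate scenarios.

RONA measures the average absolute difference between allele frequencies
predicted under current and projected future environments at climate-
associated loci — a proxy for the allele-frequency change a population
must realize to track its climate.  The workflow is:

1. :func:`prune_env` — greedily drop one member of every environmental
   variable pair with |Pearson r| above a threshold (default 0.8), keeping
   the higher-priority variable.
2. :func:`fit_freq_env` — per candidate SNP, ordinary least squares of
   allele frequency (or individual dosage/2) on its associated variable.
3. :func:`compute_rona` — per population and variable, the r^2-weighted
   (or unweighted) mean of |predicted future - predicted current|
   frequency, predictions clipped to [0, 1] by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .filters import allele_freq
from .io_formats import MISSING, EnvTable, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class EnvPruneConfig:
    max_abs_corr: float = 0.8
    priority: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.max_abs_corr <= 1.0:
            raise ValueError("max_abs_corr must be in (0, 1]")


@dataclass
class RonaConfig:
    unit: str = "population"        # "population" | "individual"
    weighting: str = "r2"           # "r2" | "uniform"
    min_r2: float = 0.0
    clip_predictions: bool = True

    def __post_init__(self) -> None:
        if self.unit not in ("population", "individual"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.weighting not in ("r2", "uniform"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if not 0.0 <= self.min_r2 < 1.0:
            raise ValueError("min_r2 must be in [0, 1)")


@dataclass
class RonaReport:
    """Per-(population, variable, scenario) RONA with per-SNP model detail."""

    summary: pd.DataFrame   # population, variable, scenario, rona, n_snps, mean_r2
    per_snp: pd.DataFrame   # variable, snp_index, slope, intercept, r2

    def value(self, population: str, variable: str, scenario: str) -> float:
        s = self.summary
        row = s[
            (s["population"] == population)
            & (s["variable"] == variable)
            & (s["scenario"] == scenario)
        ]
        return float(row["rona"].iloc[0])


# ---------------------------------------------------------------------
# Environmental variable pruning
# ---------------------------------------------------------------------

def prune_env(
    env: EnvTable, cfg: EnvPruneConfig | None = None
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy correlation pruning of the current-layer variables.

    While any retained pair has |Pearson r| > ``max_abs_corr`` over sites,
    the pair with the largest |r| is resolved by dropping its lower-
    priority member (priority tie: the lexicographically later name).
    Without user-supplied priorities, a variable's priority is minus its
    mean |r| with the other variables, so the most redundant is dropped
    first.  Returns (retained variables, log of (dropped, kept, r)).
    """
    cfg = cfg or EnvPruneConfig()
    cur = env.layer("current")
    if len(cur) < 2:
        raise ValueError("environment pruning needs >= 2 sites")
    names = list(env.variables)
    corr = cur.corr().to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    if cfg.priority is not None:
        prio = {v: cfg.priority.get(v, -np.inf) for v in names}
    else:
        k = len(names)
        mean_abs = (np.abs(corr).sum(axis=1) - 1.0) / max(k - 1, 1)
        prio = {v: -mean_abs[i] for i, v in enumerate(names)}

    alive = {v: True for v in names}
    dropped_log: list[tuple[str, str, float]] = []
    idx = {v: i for i, v in enumerate(names)}
    while True:
        live = [v for v in names if alive[v]]
        best = None
        for a_i, a in enumerate(live):
            for b in live[a_i + 1 :]:
                r = corr[idx[a], idx[b]]
                if abs(r) > cfg.max_abs_corr and (
                    best is None or abs(r) > abs(best[2])
                ):
                    best = (a, b, r)
        if best is None:
            break
        a, b, r = best
        if prio[a] < prio[b]:
            drop, keep = a, b
        elif prio[b] < prio[a]:
            drop, keep = b, a
        else:  # equal priority: drop the lexicographically later name
            drop, keep = max(a, b), min(a, b)
        alive[drop] = False
        dropped_log.append((drop, keep, float(r)))
    return [v for v in names if alive[v]], dropped_log


# ---------------------------------------------------------------------
# Per-SNP frequency ~ environment models
# ---------------------------------------------------------------------

def fit_freq_env(
    g: GenotypeMatrix,
    env: EnvTable,
    candidates: dict[str, np.ndarray],
    cfg: RonaConfig | None = None,
) -> pd.DataFrame:
    """Least-squares line per candidate SNP against its variable.

    ``candidates`` maps variable name -> SNP indices.  The response is the
    per-population ALT frequency (unit="population") or dosage/2 per
    individual (unit="individual").  Returns a frame with one row per
    (variable, SNP): slope, intercept, r2.
    """
    cfg = cfg or RonaConfig()
    if cfg.unit == "population":
        pops = g.populations
        if len(pops) < 3:
            raise ValueError("population-level fits need >= 3 populations")
        freqs = allele_freq(g, grouping="by-population")
        resp = np.vstack([freqs[p] for p in pops])           # (units, snps)
        env_rows = [env.site_ids.index(p) for p in pops]
    else:
        x = g.dosages.astype(float)
        x[g.dosages == MISSING] = np.nan
        resp = x / 2.0                                        # (units, snps)
        env_rows = [env.site_ids.index(p) for p in g.pop_of_sample]

    rows = []
    for v, idx in candidates.items():
        e = env.values["current"][env_rows, env.variables.index(v)]
        if np.std(e) == 0.0:
            raise ValueError(f"variable {v!r} has zero variance across units")
        for j in np.atleast_1d(idx):
            y = resp[:, int(j)]
            ok = ~np.isnan(y)
            if ok.sum() < 3:
                raise ValueError(f"SNP {j}: fewer than 3 units with data")
            slope, intercept, r2 = _ols_line(e[ok], y[ok])
            rows.append((v, int(j), slope, intercept, r2))
    return pd.DataFrame(
        rows, columns=["variable", "snp_index", "slope", "intercept", "r2"]
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    syy = ((y - ym) ** 2).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 0.0 if syy == 0.0 else float((sxy * sxy) / (sxx * syy))
    return float(slope), float(intercept), r2


# ---------------------------------------------------------------------
# RONA
# ---------------------------------------------------------------------

def compute_rona(
    models: pd.DataFrame,
    env: EnvTable,
    scenario: str,
    cfg: RonaConfig | None = None,
    g: GenotypeMatrix | None = None,
) -> RonaReport:
    """Weighted mean |predicted future - predicted current| frequency.

    For unit="individual" a GenotypeMatrix is required to map individuals
    to sites; the per-population report is then the within-population mean
    of individual values (with one site per population the two units give
    identical numbers).  Variables whose retained SNP set is empty are
    reported as NaN and logged.
    """
    cfg = cfg or RonaConfig()
    if scenario not in env.scenarios:
        raise ValueError(f"scenario {scenario!r} absent from env table")
    models = models[models["r2"] >= cfg.min_r2]
    pops = list(env.site_ids)
    rows = []
    for v, sub in _group_all(models, "variable"):
        if sub.empty:
            logger.warning("variable %s: no SNP model passed min_r2", v)
            for p in pops:
                rows.append((p, v, scenario, np.nan, 0, np.nan))
            continue
        jv = env.variables.index(v)
        slopes = sub["slope"].to_numpy()
        inter = sub["intercept"].to_numpy()
        w = sub["r2"].to_numpy() if cfg.weighting == "r2" else np.ones(len(sub))
        wsum = w.sum()
        e_cur = env.values["current"][:, jv]
        e_fut = env.values[scenario][:, jv]
        f_cur = inter[None, :] + np.outer(e_cur, slopes)   # (sites, snps)
        f_fut = inter[None, :] + np.outer(e_fut, slopes)
        if cfg.clip_predictions:
            f_cur = np.clip(f_cur, 0.0, 1.0)
            f_fut = np.clip(f_fut, 0.0, 1.0)
        per_site = (np.abs(f_fut - f_cur) @ w) / wsum if wsum > 0 else np.full(
            len(pops), np.nan
        )
        mean_r2 = float(sub["r2"].mean())
        if cfg.unit == "individual":
            if g is None:
                raise ValueError("unit='individual' requires the genotype matrix")
            site_of = {s: i for i, s in enumerate(env.site_ids)}
            for p in pops:
                members = [i for i in range(g.n_samples) if g.pop_of_sample[i] == p]
                vals = [per_site[site_of[p]] for _ in members]
                rona = float(np.mean(vals)) if vals else np.nan
                rows.append((p, v, scenario, rona, len(sub), mean_r2))
        else:
            for i, p in enumerate(pops):
                rows.append((p, v, scenario, float(per_site[i]), len(sub), mean_r2))
    summary = pd.DataFrame(
        rows,
        columns=["population", "variable", "scenario", "rona", "n_snps", "mean_r2"],
    )
    return RonaReport(summary=summary, per_snp=models.reset_index(drop=True))


def _group_all(df: pd.DataFrame, col: str):
    for v, sub in df.groupby(col, sort=False):
        yield v, sub
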