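"""SNP-level filters: missingness, minor allele frequency, windowed LD pruning.

The defaults reproduce the standard resequencing workflow: drop SNPs with
genotype missing rate > 0.1 or MAF < 0.05, then prune linkage disequilibrium
in sliding windows of 50 SNPs advanced by 10 at r^2 > 0.1 (the PLINK
``indep-pairwise 50 10 0.1`` convention).  r^2 is the squared Pearson
correlation of genotype dosages over pairwise-complete samples — the data
are unphased, so haplotype r^2 is never used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class FilterConfig:
    max_missing_rate: float = 0.1
    min_maf: float = 0.05
    ld_window_snps: int = 50
    ld_step_snps: int = 10
    ld_r2_threshold: float = 0.1

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "ld_r2_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.ld_window_snps >= self.ld_step_snps >= 1:
            raise ValueError("require ld_window_snps >= ld_step_snps >= 1")


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_missing_maf`."""

    n_input: int
    n_removed_missing: int
    n_removed_maf: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed_missing - self.n_removed_maf


def allele_freq(
    g: GenotypeMatrix, grouping: str = "none"
) -> np.ndarray | dict[str, np.ndarray]:
    """ALT allele frequency per SNP: sum(dosages) / (2 * non-missing count).

    ``grouping="none"`` returns one frequency vector over all samples;
    ``grouping="by-population"`` returns ``{population: vector}``.  SNPs with
    no non-missing genotype in a group get NaN.
    """
    if grouping == "none":
        return _freq(g.dosages)
    if grouping == "by-population":
        return {p: _freq(g.dosages[g.samples_of_pop(p), :]) for p in g.populations}
    raise ValueError(f"unknown grouping {grouping!r}")


def _freq(dosages: np.ndarray) -> np.ndarray:
    obs = dosages != MISSING
    n_called = obs.sum(axis=0)
    alt = np.where(obs, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = alt / (2.0 * n_called)
    return np.where(n_called > 0, f, np.nan)


def missing_rate(g: GenotypeMatrix) -> np.ndarray:
    return (g.dosages == MISSING).mean(axis=0)


def filter_missing_maf(
    g: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop SNPs failing the missingness then the MAF rule.

    Missingness is applied first; MAF = min(f, 1-f) is computed on the
    non-missing genotypes of the surviving SNPs.  Idempotent.
    """
    cfg = cfg or FilterConfig()
    miss_ok = missing_rate(g) <= cfg.max_missing_rate
    f = _freq(g.dosages)
    maf = np.minimum(f, 1.0 - f)
    maf_ok = np.where(np.isnan(maf), False, maf >= cfg.min_maf)
    keep = miss_ok & maf_ok
    report = FilterReport(
        n_input=g.n_snps,
        n_removed_missing=int((~miss_ok).sum()),
        n_removed_maf=int((miss_ok & ~maf_ok).sum()),
    )
    return g.take_snps(np.flatnonzero(keep)), report


def dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; 0.0 if either is constant there."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    sx = xs.std()
    sy = ys.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy)
    return float(r * r)


def _window_r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise dosage r^2 for the SNP columns of ``dosages``.

    Fast path (no missing calls) uses one correlation matrix; otherwise
    falls back to pairwise-complete computation.
    """
    if (dosages == MISSING).any():
        w = dosages.shape[1]
        out = np.zeros((w, w))
        for a in range(w):
            for b in range(a + 1, w):
                out[a, b] = out[b, a] = dosage_r2(dosages[:, a], dosages[:, b])
        return out
    x = dosages.astype(float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    w = x.shape[1]
    out = np.zeros((w, w))
    if keep.sum() >= 2:
        xn = x[:, keep] / sd[keep]
        c = (xn.T @ xn) / x.shape[0]
        sub = np.clip(c * c, 0.0, 1.0)
        np.fill_diagonal(sub, 0.0)
        out[np.ix_(keep, keep)] = sub
    return out


def ld_prune(
    g: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Windowed LD pruning over (chrom, pos)-sorted SNPs.

    Sliding windows of ``ld_window_snps`` SNPs advance by ``ld_step_snps``
    per chromosome.  Within a window, while any pair of kept SNPs exceeds
    ``ld_r2_threshold``, the currently highest-r^2 pair is resolved by
    removing its lower-MAF member (MAF tie: the later-positioned SNP).
    Returns the pruned matrix and the indices (into ``g``) of removed SNPs.
    """
    cfg = cfg or FilterConfig()
    f = _freq(g.dosages)
    maf = np.minimum(f, 1.0 - f)
    removed = np.zeros(g.n_snps, dtype=bool)

    for c in dict.fromkeys(g.chrom):
        cidx = np.flatnonzero(g.chrom == c)
        start = 0
        while True:
            widx = cidx[start : start + cfg.ld_window_snps]
            if len(widx) >= 2:
                _prune_window(g.dosages, widx, maf, cfg.ld_r2_threshold, removed)
            if start + cfg.ld_window_snps >= len(cidx):
                break
            start += cfg.ld_step_snps
    kept = np.flatnonzero(~removed)
    return g.take_snps(kept), np.flatnonzero(removed)


def _prune_window(
    dosages: np.ndarray,
    widx: np.ndarray,
    maf: np.ndarray,
    thresh: float,
    removed: np.ndarray,
) -> None:
    live = [i for i in widx if not removed[i]]
    if len(live) < 2:
        return
    sub = _window_r2_matrix(dosages[:, live])
    alive = np.ones(len(live), dtype=bool)
    while True:
        m = np.where(np.outer(alive, alive), sub, 0.0)
        a, b = np.unravel_index(np.argmax(m), m.shape)
        if m[a, b] <= thresh:
            break
        ia, ib = live[a], live[b]
        # drop the lower-MAF member; tie -> the later-positioned SNP
        if maf[ia] < maf[ib] or (maf[ia] == maf[ib] and ia > ib):
            drop_local, drop_global = a, ia
        else:
            drop_local, drop_global = b, ib
        alive[drop_local] = False
        removed[drop_global] = True
        if alive.sum() < 2:
            break
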