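"""Composite mu-statistic selective-sweep scan over sliding SNP windows.

A hard sweep leaves three local signatures: a deficit of polymorphism, a
site frequency spectrum shifted toward low- and high-frequency derived
variants, and elevated linkage disequilibrium on either flank of the
selected site with reduced LD across it.  Each sliding window of W SNPs is
scored by one factor per signature and their product mu:

* ``mu_var  = ((p_W - p_1) / R) * (S / W)`` — the window's bp span relative
  to the chromosome's average SNP spacing (R = analyzed chromosome span,
  S = its SNP count); neutral expectation ~ 1, larger where W SNPs stretch
  over disproportionately many bp.
* ``mu_sfs  = (c_low + c_high) / W`` — fraction of window SNPs whose derived
  count is <= k_low or >= n - k_low (REF is taken as ancestral); in folded
  mode, the fraction whose minor count is <= k_low.
* ``mu_ld   = ((rbar2_L + rbar2_R) / 2) / (rbar2_cross + eps)`` — mean
  pairwise dosage r^2 within each half-window over the mean r^2 between
  halves.

Windows above the genome-wide top quantile of mu (default top 0.05%) are
merged into candidate sweep regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .filters import _window_r2_matrix
from .io_formats import MISSING, GenotypeMatrix, Region

logger = logging.getLogger(__name__)


@dataclass
class SweepConfig:
    window_snps: int = 50
    k_low: int = 1
    top_quantile: float = 0.0005
    ld_epsilon: float = 1e-6
    polarized: bool = True

    def __post_init__(self) -> None:
        if self.window_snps < 4:
            raise ValueError("window_snps must be >= 4")
        if self.window_snps % 2:
            raise ValueError("window_snps must be even (half-window LD split)")
        if not 0.0 < self.top_quantile < 1.0:
            raise ValueError("top_quantile must be in (0, 1)")


@dataclass
class SweepScan:
    """Per-window mu factors plus the genome-wide threshold and regions."""

    windows: pd.DataFrame          # chrom, start, end, center, mu_var, mu_sfs, mu_ld, mu
    threshold: float
    regions: list[Region]
    n_snps_in_regions: int = 0


def mu_var(window_pos: np.ndarray, chrom_span: float, chrom_snp_count: int) -> float:
    """Polymorphism-deficit factor for one window of SNP positions."""
    w = len(window_pos)
    if chrom_span <= 0:
        raise ValueError("chromosome span must be positive")
    if chrom_snp_count < w:
        raise ValueError("chromosome SNP count smaller than the window")
    span = float(window_pos[-1] - window_pos[0])
    return (span / chrom_span) * (chrom_snp_count / w)


def _derived_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP derived (ALT) allele count and haplotype count, ignoring
    missing calls."""
    obs = dosages != MISSING
    derived = np.where(obs, dosages, 0).sum(axis=0)
    n_hap = 2 * obs.sum(axis=0)
    return derived, n_hap


def mu_sfs(
    window_dosages: np.ndarray, k_low: int = 1, polarized: bool = True
) -> float:
    """SFS-shift factor: fraction of window SNPs in the extreme frequency
    classes.  Requires >= 4 haplotypes at every SNP."""
    derived, n_hap = _derived_counts(window_dosages)
    if (n_hap < 4).any():
        raise ValueError("mu_sfs requires >= 4 haplotypes per SNP")
    w = window_dosages.shape[1]
    if polarized:
        extreme = (derived <= k_low) | (derived >= n_hap - k_low)
    else:
        minor = np.minimum(derived, n_hap - derived)
        extreme = minor <= k_low
    return float(extreme.sum()) / w


def mu_ld(window_dosages: np.ndarray, ld_epsilon: float = 1e-6) -> float:
    """Flanking-LD factor: within-half mean r^2 over cross-half mean r^2."""
    w = window_dosages.shape[1]
    half = w // 2
    r2 = _window_r2_matrix(window_dosages)
    iu_l = np.triu_indices(half, k=1)
    left = r2[:half, :half][iu_l]
    right = r2[half:, half:][np.triu_indices(w - half, k=1)]
    cross = r2[:half, half:]
    within = (left.mean() + right.mean()) / 2.0 if half > 1 else 0.0
    return float(within / (cross.mean() + ld_epsilon))


def mu_scan(g: GenotypeMatrix, cfg: SweepConfig | None = None) -> SweepScan:
    """Scan all chromosomes with one-SNP-step windows; threshold genome-wide.

    Chromosomes with fewer than ``window_snps`` SNPs are skipped with a
    warning.  Windows whose mu exceeds the (1 - top_quantile) empirical
    quantile are merged (by SNP-span overlap) into significant regions.
    The scan is invariant to sample order.
    """
    cfg = cfg or SweepConfig()
    w = cfg.window_snps
    rows = []
    for c in dict.fromkeys(g.chrom):
        cidx = np.flatnonzero(g.chrom == c)
        if len(cidx) < w:
            logger.warning("chromosome %s has %d < %d SNPs; skipped", c, len(cidx), w)
            continue
        pos = g.pos[cidx].astype(float)
        dos = g.dosages[:, cidx]
        span = float(pos[-1] - pos[0])
        s_count = len(cidx)
        derived, n_hap = _derived_counts(dos)
        if cfg.polarized:
            extreme = (derived <= cfg.k_low) | (derived >= n_hap - cfg.k_low)
        else:
            minor = np.minimum(derived, n_hap - derived)
            extreme = minor <= cfg.k_low
        ext_cum = np.concatenate([[0], np.cumsum(extreme)])
        for i in range(s_count - w + 1):
            win = slice(i, i + w)
            mv = (pos[i + w - 1] - pos[i]) / span * (s_count / w)
            ms = (ext_cum[i + w] - ext_cum[i]) / w
            ml = mu_ld(dos[:, win], cfg.ld_epsilon)
            rows.append(
                (
                    c,
                    pos[i],
                    pos[i + w - 1],
                    (pos[i] + pos[i + w - 1]) / 2.0,
                    mv,
                    ms,
                    ml,
                    mv * ms * ml,
                )
            )
    windows = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "center", "mu_var", "mu_sfs", "mu_ld", "mu"],
    )
    if windows.empty:
        return SweepScan(windows=windows, threshold=np.nan, regions=[])
    threshold = float(np.quantile(windows["mu"].to_numpy(), 1.0 - cfg.top_quantile))
    regions = _merge_significant(windows, threshold)
    n_in = _count_snps_in_regions(g, regions)
    return SweepScan(
        windows=windows, threshold=threshold, regions=regions, n_snps_in_regions=n_in
    )


def _merge_significant(windows: pd.DataFrame, threshold: float) -> list[Region]:
    sig = windows[windows["mu"] >= threshold]
    regions: list[Region] = []
    for c, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        cur_score = 0.0
        for _, row in grp.iterrows():
            s, e = int(row["start"]) - 1, int(row["end"])  # BED half-open
            if cur_start is None:
                cur_start, cur_end, cur_score = s, e, row["mu"]
            elif s < cur_end:  # SNP-span overlap
                cur_end = max(cur_end, e)
                cur_score = max(cur_score, row["mu"])
            else:
                regions.append(Region(str(c), cur_start, cur_end, cur_score))
                cur_start, cur_end, cur_score = s, e, row["mu"]
        if cur_start is not None:
            regions.append(Region(str(c), cur_start, cur_end, cur_score))
    return regions


def _count_snps_in_regions(g: GenotypeMatrix, regions: list[Region]) -> int:
    total = 0
    for r in regions:
        on = g.chrom == r.chrom
        total += int(((g.pos > r.start) & (g.pos <= r.end) & on).sum())
    return total
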