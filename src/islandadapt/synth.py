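"""Synthetic inputs carrying the statistical structure the pipeline assumes.

Three generators:

* :func:`sim_structured_genotypes` — island-model genotypes under the
  Balding–Nichols model: per-SNP ancestral frequency p0 ~ U(0.05, 0.95),
  deme frequency ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F) with F the target F_ST,
  genotypes binomial.  Defaults mirror the sampling design the pipeline was
  built around: 5 populations x 6 diploid individuals.
* :func:`sim_env` / :func:`inject_env_association` — multivariate-normal
  bioclimatic tables with current and future (SSP-style) layers, and loci
  whose deme allele frequencies are rebuilt as a linear function of a
  standardized environmental variable (the exact monotone relationship the
  downstream association and RONA models assume).
* :func:`sim_sweep` — discrete-generation forward Wright–Fisher simulation
  of a hard selective sweep with recombination and infinite-sites mutation,
  conditioned on fixation by restarting.  Population size and per-bp rates
  are desk-scaled (N is small, mu is scaled up so that theta = 4*N*mu stays
  in a realistic range; the unscaled per-generation rate for the
  target species is kept in :data:`UNSCALED_MUTATION_RATE`).

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import EnvTable, GenotypeMatrix

#: Per-bp per-generation mutation rate reported for the target species; forward runs scale this up as N is scaled down so
#: the population-scaled rate theta = 4*N*mu is preserved.
UNSCALED_MUTATION_RATE: float = 8.21e-10

#: Default population labels (the five sampled sites).
DEFAULT_POPS: tuple[str, ...] = ("DLS", "JFL", "QSX", "QXL", "SMX")

#: The seven weakly correlated bioclimatic variables used downstream.
DEFAULT_ENV_VARS: tuple[str, ...] = (
    "BIO2", "BIO3", "BIO7", "BIO8", "BIO9", "BIO14", "BIO18",
)


# ---------------------------------------------------------------------
# Structured genotypes (Balding–Nichols)
# ---------------------------------------------------------------------

@dataclass
class StructureSimConfig:
    n_pops: int = 5
    n_per_pop: int = 6
    n_snps: int = 10_000
    fst: float = 0.1
    n_chroms: int = 12
    chrom_length_bp: int = 5_000_000
    missing_rate: float = 0.0
    latent_rank: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError("n_pops must be >= 2")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.latent_rank is not None and not (
            1 <= self.latent_rank < self.n_pops
        ):
            raise ValueError("latent_rank must be in [1, n_pops)")


def sim_structured_genotypes(cfg: StructureSimConfig) -> GenotypeMatrix:
    """Structured genotypes for ``n_pops`` demes at target F_ST.

    By default deme frequencies follow the Balding–Nichols Beta model,
    whose per-locus deme deviations are independent (full-rank structure
    in deme space).  With ``latent_rank = K`` the deviations instead come
    from a rank-K factor model — deme frequency = p0 plus a K-factor
    linear term with variance matched to ``fst`` — so the population
    structure is exactly the low-rank kind a latent-factor association
    model assumes it can absorb.
    """
    rng = np.random.default_rng(cfg.seed)
    p0 = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    F = cfg.fst
    if cfg.latent_rank is None:
        a = p0 * (1.0 - F) / F
        b = (1.0 - p0) * (1.0 - F) / F
        # deme frequencies: (n_pops, n_snps)
        p_deme = rng.beta(a[None, :], b[None, :], size=(cfg.n_pops, cfg.n_snps))
    else:
        K = cfg.latent_rank
        scores = rng.standard_normal((cfg.n_pops, K))
        scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=0)
        sigma = np.sqrt(F * p0 * (1.0 - p0) / K)
        loadings = rng.standard_normal((K, cfg.n_snps)) * sigma[None, :]
        dev = scores @ loadings
        # keep frequencies inside (0.01, 0.99) by rescaling each locus's
        # deviation profile (clipping would break the low-rank structure)
        room = np.minimum(p0, 1.0 - p0) - 0.01
        amax = np.abs(dev).max(axis=0)
        scale = np.minimum(1.0, room / np.maximum(amax, 1e-12))
        p_deme = p0[None, :] + dev * scale[None, :]
    n = cfg.n_pops * cfg.n_per_pop
    dosages = np.empty((n, cfg.n_snps), dtype=np.int8)
    for d in range(cfg.n_pops):
        rows = slice(d * cfg.n_per_pop, (d + 1) * cfg.n_per_pop)
        dosages[rows] = rng.binomial(
            2, p_deme[d][None, :], size=(cfg.n_per_pop, cfg.n_snps)
        )
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = -1

    chrom_ids, pos = _random_positions(
        rng, cfg.n_snps, cfg.n_chroms, cfg.chrom_length_bp
    )
    pops = _pop_labels(cfg.n_pops)
    sample_ids = [
        f"{pops[d]}_{i + 1}" for d in range(cfg.n_pops) for i in range(cfg.n_per_pop)
    ]
    return GenotypeMatrix(
        dosages=dosages,
        chrom=chrom_ids,
        pos=pos,
        ref_allele=np.full(cfg.n_snps, "A", dtype=object),
        alt_allele=np.full(cfg.n_snps, "T", dtype=object),
        sample_ids=np.array(sample_ids, dtype=object),
        pop_of_sample=np.array(
            [pops[d] for d in range(cfg.n_pops) for _ in range(cfg.n_per_pop)],
            dtype=object,
        ),
    )


def _pop_labels(n_pops: int) -> list[str]:
    if n_pops <= len(DEFAULT_POPS):
        return list(DEFAULT_POPS[:n_pops])
    return [f"pop{i + 1}" for i in range(n_pops)]


def _random_positions(
    rng: np.random.Generator, n_snps: int, n_chroms: int, chrom_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform SNP placement on ``n_chroms`` chromosomes, sorted, no ties."""
    chrom_idx = np.sort(rng.integers(0, n_chroms, size=n_snps))
    chroms = np.array([f"chr{i + 1}" for i in chrom_idx], dtype=object)
    pos = np.empty(n_snps, dtype=np.int64)
    for i in range(n_chroms):
        m = chrom_idx == i
        k = int(m.sum())
        if k == 0:
            continue
        # sample without replacement so positions are strictly increasing
        p = rng.choice(chrom_len, size=k, replace=False) + 1
        pos[m] = np.sort(p)
    return chroms, pos


# ---------------------------------------------------------------------
# Environment tables and planted associations
# ---------------------------------------------------------------------

@dataclass
class GeaSimConfig:
    n_adaptive_loci: int = 100
    slope_range: tuple[float, float] = (0.1, 0.3)
    env_correlation: float = 0.3
    variables: tuple[str, ...] = DEFAULT_ENV_VARS
    future_shifts: dict = field(
        default_factory=lambda: {"SSP126": 0.5, "SSP585": 1.5}
    )
    clamp: tuple[float, float] = (0.02, 0.98)
    seed: int = 0


def sim_env(cfg: GeaSimConfig, n_pops: int = 5) -> EnvTable:
    """Current-layer site environments from an equicorrelated multivariate
    normal; future layers add per-variable deterministic shifts."""
    k = len(cfg.variables)
    corr = np.full((k, k), cfg.env_correlation)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            f"target correlation {cfg.env_correlation} gives a "
            "non-positive-definite matrix"
        ) from e
    rng = np.random.default_rng(cfg.seed)
    current = rng.standard_normal((n_pops, k)) @ chol.T
    values = {"current": current}
    for scen, shift in cfg.future_shifts.items():
        values[scen] = current + np.broadcast_to(
            np.asarray(shift, dtype=float), (k,)
        )
    return EnvTable(
        site_ids=_pop_labels(n_pops),
        variables=list(cfg.variables),
        values=values,
    )


def inject_env_association(
    g: GenotypeMatrix, env: EnvTable, cfg: GeaSimConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Rebuild ``n_adaptive_loci`` random loci so that deme allele
    frequencies follow a linear function of one standardized variable.

    For each chosen locus j with variable v, the deme frequency becomes
    ``clamp(p0_j + b_j * z(e_deme,v))`` with z the standardized current
    layer and b_j drawn from ``slope_range`` with random sign; genotypes
    are then redrawn binomially.  Returns the modified matrix and a truth
    table (snp_index, chrom, pos, variable, slope) for power/FDR scoring.
    """
    if cfg.n_adaptive_loci > g.n_snps:
        raise ValueError(
            f"{cfg.n_adaptive_loci} adaptive loci requested but only "
            f"{g.n_snps} SNPs available"
        )
    pops = g.populations
    missing = [p for p in pops if p not in env.site_ids]
    if missing:
        raise ValueError(f"populations {missing} absent from env table")
    rng = np.random.default_rng(cfg.seed + 1)
    loci = np.sort(rng.choice(g.n_snps, size=cfg.n_adaptive_loci, replace=False))
    var_idx = rng.integers(0, len(env.variables), size=cfg.n_adaptive_loci)
    lo, hi = cfg.slope_range
    slopes = rng.uniform(lo, hi, size=cfg.n_adaptive_loci)
    slopes *= rng.choice([-1.0, 1.0], size=cfg.n_adaptive_loci)

    cur = env.layer("current")
    z = (cur - cur.mean(axis=0)) / cur.std(axis=0, ddof=0)
    dosages = g.dosages.copy()
    obs = dosages != -1
    lo_c, hi_c = cfg.clamp
    rows = {p: g.samples_of_pop(p) for p in pops}
    p0_of_locus = []
    for j, vi, b in zip(loci, var_idx, slopes):
        col = dosages[:, j]
        ok = obs[:, j]
        p0 = col[ok].sum() / (2.0 * ok.sum())
        p0_of_locus.append(p0)
        for p in pops:
            zval = z.loc[p, env.variables[vi]]
            freq = float(np.clip(p0 + b * zval, lo_c, hi_c))
            r = rows[p]
            new = rng.binomial(2, freq, size=len(r)).astype(np.int8)
            new[~obs[r, j]] = -1  # preserve missing pattern
            dosages[r, j] = new

    truth = pd.DataFrame(
        {
            "snp_index": loci,
            "chrom": g.chrom[loci],
            "pos": g.pos[loci],
            "variable": [env.variables[v] for v in var_idx],
            "slope": slopes,
            "p0": p0_of_locus,
        }
    )
    out = GenotypeMatrix(
        dosages=dosages,
        chrom=g.chrom,
        pos=g.pos,
        ref_allele=g.ref_allele,
        alt_allele=g.alt_allele,
        sample_ids=g.sample_ids,
        pop_of_sample=g.pop_of_sample,
    )
    return out, truth


# ---------------------------------------------------------------------
# Forward Wright–Fisher hard sweep
# ---------------------------------------------------------------------

@dataclass
class SweepSimConfig:
    n_diploid: int = 200
    seq_len: int = 200_000
    mu: float = 2e-6          # desk-scaled; see UNSCALED_MUTATION_RATE
    rho: float = 5e-7
    s: float = 0.05
    sel_pos: float | None = None   # default: chromosome midpoint
    n_sample: int = 50
    burn_in_gens: int | None = None  # default: 10 * n_diploid
    max_restarts: int = 500
    max_sweep_gens: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.sel_pos is None:
            self.sel_pos = self.seq_len / 2
        if not 0 <= self.sel_pos < self.seq_len:
            raise ValueError("sel_pos must lie in [0, seq_len)")
        if self.burn_in_gens is None:
            self.burn_in_gens = 10 * self.n_diploid
        if self.n_sample > 2 * self.n_diploid:
            raise ValueError("cannot sample more haplotypes than 2N")


class FixationError(RuntimeError):
    """The beneficial allele failed to fix within ``max_restarts`` attempts."""


def sim_sweep(cfg: SweepSimConfig) -> tuple[GenotypeMatrix, float]:
    """Forward Wright–Fisher simulation of a hard sweep.

    A neutral population of ``n_diploid`` individuals is burned in for
    ``burn_in_gens`` generations under infinite-sites mutation (rate ``mu``
    per bp per generation) and uniform recombination (``rho`` per bp).
    A single beneficial copy with multiplicative per-copy advantage
    ``1 + s`` is then introduced at ``sel_pos`` and the run restarts from
    the burned-in state until it fixes.  ``n_sample`` haplotypes drawn at
    fixation are paired into diploids.  With ``s = 0`` the sample is taken
    directly after burn-in (neutral control).

    Returns the sampled genotypes and the true position of the beneficial
    allele.
    """
    ss = np.random.SeedSequence(cfg.seed)
    burn_key, sample_key, *attempt_keys = ss.spawn(2 + cfg.max_restarts)
    rng = np.random.default_rng(burn_key)
    n_hap = 2 * cfg.n_diploid
    H = np.zeros((n_hap, 0), dtype=bool)
    positions = np.empty(0, dtype=float)
    mu_total = cfg.mu * cfg.seq_len       # per-haplotype per-generation
    r_total = cfg.rho * cfg.seq_len       # expected crossovers per gamete

    for _ in range(cfg.burn_in_gens):
        H, positions, _ = _wf_generation(
            H, positions, rng, mu_total, r_total, cfg.seq_len, None, 0.0
        )

    if cfg.s > 0:
        H, positions = _run_sweep(H, positions, cfg, attempt_keys)

    rng_s = np.random.default_rng(sample_key)
    hap_idx = rng_s.choice(n_hap, size=cfg.n_sample, replace=False)
    return _haplotypes_to_matrix(H[hap_idx], positions, cfg), float(cfg.sel_pos)


def _run_sweep(H0, pos0, cfg, attempt_keys):
    n_hap = 2 * cfg.n_diploid
    mu_total = cfg.mu * cfg.seq_len
    r_total = cfg.rho * cfg.seq_len
    for attempt, key in enumerate(attempt_keys):
        rng = np.random.default_rng(key)
        # append the beneficial column on a copy of the standing variation
        ben_col = np.zeros((n_hap, 1), dtype=bool)
        ben_col[rng.integers(n_hap), 0] = True
        H = np.concatenate([H0.copy(), ben_col], axis=1)
        positions = np.append(pos0, float(cfg.sel_pos))
        ben_idx = H.shape[1] - 1
        for _ in range(cfg.max_sweep_gens):
            H, positions, ben_idx = _wf_generation(
                H, positions, rng, mu_total, r_total, cfg.seq_len,
                ben_idx, cfg.s,
            )
            count = int(H[:, ben_idx].sum())
            if count == 0:
                break
            if count == n_hap:
                # fixed: the beneficial column itself is no longer segregating
                keep = np.ones(H.shape[1], dtype=bool)
                keep[ben_idx] = False
                return H[:, keep], positions[keep]
    raise FixationError(
        f"beneficial allele failed to fix in {cfg.max_restarts} attempts"
    )


def _wf_generation(H, positions, rng, mu_total, r_total, seq_len, ben_idx, s):
    """One discrete Wright–Fisher generation; returns updated state.

    ``ben_idx`` indexes the beneficial column (or None).  The beneficial
    column is exempt from the fixed/lost purge so callers can watch it.
    """
    n_hap = H.shape[0]
    n_dip = n_hap // 2
    # --- selection + parent sampling
    if ben_idx is not None and s > 0.0:
        cnt = H[0::2, ben_idx].astype(np.int64) + H[1::2, ben_idx]
        w = (1.0 + s) ** cnt
        parents = rng.choice(n_dip, size=n_hap, p=w / w.sum())
    else:
        parents = rng.integers(0, n_dip, size=n_hap)

    # --- meiosis
    starts = rng.integers(0, 2, size=n_hap)
    n_cross = rng.poisson(r_total, size=n_hap)
    C = H[2 * parents + starts]  # copy-from-one-parent fast path
    C = np.ascontiguousarray(C)
    for i in np.flatnonzero(n_cross > 0):
        bp = rng.uniform(0.0, seq_len, size=n_cross[i])
        parity = (positions[None, :] > bp[:, None]).sum(axis=0) % 2
        h1 = H[2 * parents[i] + starts[i]]
        h2 = H[2 * parents[i] + 1 - starts[i]]
        C[i] = np.where(parity == 0, h1, h2)

    # --- mutation (infinite sites on a continuous [0, seq_len) axis)
    m = rng.poisson(mu_total * n_hap)
    if m > 0:
        newpos = rng.uniform(0.0, seq_len, size=m)
        newcols = np.zeros((n_hap, m), dtype=bool)
        newcols[rng.integers(0, n_hap, size=m), np.arange(m)] = True
        C = np.concatenate([C, newcols], axis=1)
        positions = np.append(positions, newpos)

    # --- purge fixed/lost neutral columns
    colsum = C.sum(axis=0)
    keep = (colsum > 0) & (colsum < n_hap)
    if ben_idx is not None:
        keep[ben_idx] = True
        new_ben = int(keep[:ben_idx].sum())
    else:
        new_ben = None
    return C[:, keep], positions[keep], new_ben


def _haplotypes_to_matrix(
    hap: np.ndarray, positions: np.ndarray, cfg: SweepSimConfig
) -> GenotypeMatrix:
    """Pair sampled haplotypes into diploids; keep sites segregating in the
    sample; integerize coordinates (1-based) and drop ties."""
    n_sample = hap.shape[0]
    n_dip = n_sample // 2
    hap = hap[: 2 * n_dip]
    counts = hap.sum(axis=0)
    seg = (counts > 0) & (counts < hap.shape[0])
    hap = hap[:, seg]
    positions = positions[seg]
    order = np.argsort(positions, kind="stable")
    hap = hap[:, order]
    pos_bp = np.floor(positions[order]).astype(np.int64) + 1
    uniq = np.concatenate([[True], np.diff(pos_bp) > 0])
    hap = hap[:, uniq]
    pos_bp = pos_bp[uniq]
    dosages = (hap[0::2].astype(np.int8) + hap[1::2])
    n_snps = dosages.shape[1]
    return GenotypeMatrix(
        dosages=dosages,
        chrom=np.full(n_snps, "chr1", dtype=object),
        pos=pos_bp,
        ref_allele=np.full(n_snps, "A", dtype=object),
        alt_allele=np.full(n_snps, "T", dtype=object),
        sample_ids=np.array([f"ind{i + 1}" for i in range(n_dip)], dtype=object),
        pop_of_sample=np.full(n_dip, "pop0", dtype=object),
    )
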