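"""Pipeline orchestration: one structured config, staged execution, resume.

Stage order mirrors the analysis it automates: SNP filtering, sweep scan,
environmental-variable pruning, genotype-environment association, RONA.
Each stage writes its outputs plus a small manifest holding a hash of the
parameters it ran with; re-running with an unchanged config skips stages
whose outputs and manifest are intact, so deleting one stage's outputs
re-executes only that stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filters, gea, rona, sweep
from .filters import FilterConfig
from .gea import GeaConfig
from .io_formats import (
    read_env_table,
    read_pop_map,
    read_vcf,
    write_regions,
    write_vcf,
)
from .rona import EnvPruneConfig, RonaConfig
from .sweep import SweepConfig

logger = logging.getLogger(__name__)

STAGES = ("filter", "sweep", "env_prune", "gea", "rona")


@dataclass
class PipelinePaths:
    vcf: str
    pop_map: str
    env_current: str
    outdir: str
    env_future: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    paths: PipelinePaths
    filter: FilterConfig = field(default_factory=FilterConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    gea: GeaConfig = field(default_factory=GeaConfig)
    env_prune: EnvPruneConfig = field(default_factory=EnvPruneConfig)
    rona: RonaConfig = field(default_factory=RonaConfig)
    seed: int = 0
    log_level: str = "INFO"

    def stage_params(self, stage: str) -> dict:
        cfg = {
            "filter": self.filter,
            "sweep": self.sweep,
            "env_prune": self.env_prune,
            "gea": self.gea,
            "rona": self.rona,
        }[stage]
        d = dataclasses.asdict(cfg)
        d["_seed"] = self.seed
        return d


class ConfigError(ValueError):
    """Configuration problems, with one message per offending field."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


_SECTION_TYPES = {
    "filter": FilterConfig,
    "sweep": SweepConfig,
    "gea": GeaConfig,
    "env_prune": EnvPruneConfig,
    "rona": RonaConfig,
}


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load and normalize a YAML (or dict) pipeline configuration.

    Missing required paths are errors naming the field; unknown keys are
    warnings only.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)

    errors: list[str] = []
    known_top = {"paths", "seed", "log_level", *_SECTION_TYPES}
    for k in raw:
        if k not in known_top:
            logger.warning("config: unknown key %r ignored", k)

    praw = raw.get("paths") or {}
    for req in ("vcf", "pop_map", "env_current", "outdir"):
        if req not in praw:
            errors.append(f"paths.{req} is required")
    sections = {}
    for name, typ in _SECTION_TYPES.items():
        sraw = raw.get(name) or {}
        fields = {f.name for f in dataclasses.fields(typ)}
        for k in list(sraw):
            if k not in fields:
                logger.warning("config: unknown key %s.%s ignored", name, k)
                sraw.pop(k)
        try:
            sections[name] = typ(**sraw)
        except (TypeError, ValueError) as e:
            errors.append(f"{name}: {e}")
    if errors:
        raise ConfigError(errors)

    cfg = PipelineConfig(
        paths=PipelinePaths(
            vcf=str(praw["vcf"]),
            pop_map=str(praw["pop_map"]),
            env_current=str(praw["env_current"]),
            outdir=str(praw["outdir"]),
            env_future={k: str(v) for k, v in (praw.get("env_future") or {}).items()},
        ),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        **sections,
    )
    missing = [
        f"paths.{name} does not exist: {p}"
        for name, p in [
            ("vcf", cfg.paths.vcf),
            ("pop_map", cfg.paths.pop_map),
            ("env_current", cfg.paths.env_current),
            *[(f"env_future.{k}", v) for k, v in cfg.paths.env_future.items()],
        ]
        if not Path(p).exists()
    ]
    if missing:
        raise ConfigError(missing)
    return cfg


# ---------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------

def _params_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_fresh(outdir: Path, stage: str, params: dict, outputs: list[Path]) -> bool:
    manifest = outdir / f".{stage}.manifest.json"
    if not manifest.exists() or not all(p.exists() for p in outputs):
        return False
    try:
        saved = json.loads(manifest.read_text())
    except json.JSONDecodeError:
        return False
    return saved.get("hash") == _params_hash(params)


def _write_manifest(outdir: Path, stage: str, params: dict, outputs: list[Path]) -> None:
    (outdir / f".{stage}.manifest.json").write_text(
        json.dumps(
            {"stage": stage, "hash": _params_hash(params),
             "outputs": [str(p) for p in outputs]},
            indent=2,
        )
    )


def _tsv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with path.open("w") as fh:
        fh.write(f"# islandadapt seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages into ``cfg.paths.outdir``; returns the run dir.

    Completed stages (matching manifest + outputs present) are skipped.
    """
    outdir = Path(cfg.paths.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    seed = cfg.seed

    pop_map = read_pop_map(cfg.paths.pop_map)
    g_raw = read_vcf(cfg.paths.vcf, pop_map=pop_map)
    env = read_env_table(cfg.paths.env_current, cfg.paths.env_future)

    # --- stage: filter
    f_out = [outdir / "filtered.vcf", outdir / "filter_report.tsv"]
    params = cfg.stage_params("filter")
    if _stage_fresh(outdir, "filter", params, f_out):
        logger.info("stage filter: up to date, skipping")
    else:
        logger.info("stage filter: running")
        g1, report = filters.filter_missing_maf(g_raw, cfg.filter)
        g2, pruned = filters.ld_prune(g1, cfg.filter)
        write_vcf(g2, f_out[0])
        _tsv(
            pd.DataFrame(
                {
                    "rule": ["input", "missingness", "maf", "ld_prune", "kept"],
                    "n_snps": [
                        report.n_input,
                        report.n_removed_missing,
                        report.n_removed_maf,
                        len(pruned),
                        g2.n_snps,
                    ],
                }
            ),
            f_out[1],
            seed,
        )
        _write_manifest(outdir, "filter", params, f_out)
    g = read_vcf(f_out[0], pop_map=pop_map)

    # --- stage: sweep scan
    s_out = [outdir / "sweep_windows.tsv", outdir / "sweep_regions.bed"]
    params = cfg.stage_params("sweep")
    if _stage_fresh(outdir, "sweep", params, s_out):
        logger.info("stage sweep: up to date, skipping")
    else:
        logger.info("stage sweep: running")
        scan = sweep.mu_scan(g, cfg.sweep)
        _tsv(scan.windows, s_out[0], seed)
        write_regions(scan.regions, s_out[1])
        _write_manifest(outdir, "sweep", params, s_out)

    # --- stage: environmental variable pruning
    e_out = [outdir / "env_retained.tsv"]
    params = cfg.stage_params("env_prune")
    if _stage_fresh(outdir, "env_prune", params, e_out):
        logger.info("stage env_prune: up to date, skipping")
        retained = pd.read_csv(e_out[0], sep="\t", comment="#")["variable"].tolist()
    else:
        logger.info("stage env_prune: running")
        retained, dropped = rona.prune_env(env, cfg.env_prune)
        _tsv(pd.DataFrame({"variable": retained}), e_out[0], seed)
        _write_manifest(outdir, "env_prune", params, e_out)
    env_used = env.subset_variables(retained)

    # --- stage: GEA
    g_out = [
        outdir / "gea_associations.tsv",
        outdir / "gea_candidates.tsv",
        outdir / "gea_hotspots.tsv",
    ]
    params = cfg.stage_params("gea")
    if _stage_fresh(outdir, "gea", params, g_out):
        logger.info("stage gea: up to date, skipping")
        assoc = pd.read_csv(g_out[0], sep="\t", comment="#")
        cand_df = pd.read_csv(g_out[1], sep="\t", comment="#")
    else:
        logger.info("stage gea: running")
        result = gea.fit_association(g, env_used, cfg=cfg.gea)
        union, counts = gea.candidate_union(result)
        hot, per_chrom, r, pval = gea.hotspot_windows(union, g, cfg.gea.hotspot_window)
        _tsv(result.table, g_out[0], seed)
        cand_df = result.table[result.table["candidate"]][
            ["variable", "snp_index", "chrom", "pos", "q"]
        ]
        _tsv(cand_df, g_out[1], seed)
        hot = hot.assign(chrom_size_corr_r=r, chrom_size_corr_p=pval)
        _tsv(hot, g_out[2], seed)
        _write_manifest(outdir, "gea", params, g_out)
        assoc = result.table

    # --- stage: RONA
    r_out = [outdir / "rona.tsv", outdir / "rona_models.tsv"]
    params = cfg.stage_params("rona")
    if _stage_fresh(outdir, "rona", params, r_out):
        logger.info("stage rona: up to date, skipping")
    else:
        logger.info("stage rona: running")
        candidates = {
            v: sub["snp_index"].to_numpy()
            for v, sub in cand_df.groupby("variable", sort=False)
            if v in env_used.variables
        }
        if candidates:
            models = rona.fit_freq_env(g, env_used, candidates, cfg.rona)
            reports = []
            for scen in cfg.paths.env_future:
                rep = rona.compute_rona(models, env_used, scen, cfg.rona, g)
                reports.append(rep.summary)
            summary = (
                pd.concat(reports, ignore_index=True)
                if reports
                else pd.DataFrame(
                    columns=["population", "variable", "scenario", "rona", "n_snps", "mean_r2"]
                )
            )
            _tsv(summary, r_out[0], seed)
            _tsv(models, r_out[1], seed)
        else:
            logger.warning("stage rona: no GEA candidates, writing empty reports")
            _tsv(
                pd.DataFrame(
                    columns=["population", "variable", "scenario", "rona", "n_snps", "mean_r2"]
                ),
                r_out[0],
                seed,
            )
            _tsv(
                pd.DataFrame(columns=["variable", "snp_index", "slope", "intercept", "r2"]),
                r_out[1],
                seed,
            )
        _write_manifest(outdir, "rona", params, r_out)
    return outdir
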