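"""Genotype data model and readers/writers for the formats the pipeline touches.

The central object is :class:`GenotypeMatrix`, an allele-dosage matrix
(samples x SNPs, values 0/1/2 with ``MISSING = -1``) carrying variant
coordinates and sample/population labels.  VCF positions are kept 1-based
internally, exactly as in the file; interval exports use BED conventions
(0-based, half-open).  Genotypes are treated as unphased throughout: the
phase separators ``/`` and ``|`` are read identically and only the ALT
dosage is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call (``./.``); excluded from every
#: downstream sum.
MISSING: int = -1

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to the format the reader expects."""


class EmptyInputError(ValueError):
    """An input file contained no usable records."""


@dataclass
class Region:
    """Genomic interval, 0-based half-open, with an optional score."""

    chrom: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"Region start must be < end, got [{self.start}, {self.end})"
            )

    def contains(self, chrom: str, pos_1based: int) -> bool:
        return self.chrom == chrom and self.start < pos_1based <= self.end


@dataclass
class GenotypeMatrix:
    """Biallelic-SNP dosage matrix with coordinates and population labels.

    Attributes
    ----------
    dosages
        ``(n_samples, n_snps)`` int8 array of ALT-allele counts per diploid
        genotype (0, 1, 2) with ``MISSING`` for no-calls.
    chrom, pos
        Per-SNP chromosome label and 1-based coordinate; positions are
        strictly increasing within each chromosome.
    ref_allele, alt_allele
        Per-SNP single-base alleles.  REF is treated as the ancestral
        allele wherever a derived/ancestral distinction is needed.
    sample_ids, pop_of_sample
        Per-sample identifier and population label.
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    sample_ids: np.ndarray
    pop_of_sample: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.pop_of_sample = np.asarray(self.pop_of_sample, dtype=object)
        self.validate()

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        return list(dict.fromkeys(self.pop_of_sample))

    def samples_of_pop(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.pop_of_sample == pop)

    def validate(self) -> None:
        n, s = self.dosages.shape
        if len(self.sample_ids) != n or len(self.pop_of_sample) != n:
            raise ValueError("sample annotation length mismatch")
        for arr, name in (
            (self.chrom, "chrom"),
            (self.pos, "pos"),
            (self.ref_allele, "ref_allele"),
            (self.alt_allele, "alt_allele"),
        ):
            if len(arr) != s:
                raise ValueError(f"{name} length {len(arr)} != n_snps {s}")
        ok = (self.dosages == MISSING) | (
            (self.dosages >= 0) & (self.dosages <= 2)
        )
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or the missing sentinel")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")
        if n > 0 and len(set(self.pop_of_sample)) < 1:
            raise ValueError("at least one population label required")

    # -- subsetting ----------------------------------------------------
    def take_snps(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
        )

    def take_samples(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[idx, :],
            sample_ids=self.sample_ids[idx],
            pop_of_sample=self.pop_of_sample[idx],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref_allele, other.ref_allele)
            and np.array_equal(self.alt_allele, other.alt_allele)
            and np.array_equal(self.sample_ids, other.sample_ids)
        )


@dataclass
class EnvTable:
    """Environmental variables per sampling site, one layer per scenario.

    All scenario layers share the same site and variable ordering; the
    ``"current"`` scenario is always present.
    """

    site_ids: list[str]
    variables: list[str]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "current" not in self.values:
            raise ValueError('EnvTable requires a "current" scenario layer')
        shape = (len(self.site_ids), len(self.variables))
        for name, mat in self.values.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != shape:
                raise ValueError(
                    f"scenario {name!r} has shape {mat.shape}, expected {shape}"
                )
            if np.isnan(mat).any():
                raise ValueError(f"scenario {name!r} contains missing values")
            self.values[name] = mat

    @property
    def scenarios(self) -> list[str]:
        return list(self.values)

    def layer(self, scenario: str) -> pd.DataFrame:
        return pd.DataFrame(
            self.values[scenario], index=self.site_ids, columns=self.variables
        )

    def column(self, scenario: str, variable: str) -> np.ndarray:
        j = self.variables.index(variable)
        return self.values[scenario][:, j]

    def subset_variables(self, keep: Iterable[str]) -> "EnvTable":
        keep = list(keep)
        idx = [self.variables.index(v) for v in keep]
        return EnvTable(
            site_ids=list(self.site_ids),
            variables=keep,
            values={k: v[:, idx].copy() for k, v in self.values.items()},
        )

    def expand_to_samples(
        self, pop_of_sample: np.ndarray, scenario: str = "current"
    ) -> pd.DataFrame:
        """Per-sample environment: each sample gets its population's values."""
        row = {s: i for i, s in enumerate(self.site_ids)}
        try:
            ridx = [row[p] for p in pop_of_sample]
        except KeyError as e:
            raise ValueError(f"population {e} not found among env sites") from e
        return pd.DataFrame(
            self.values[scenario][ridx, :], columns=self.variables
        )


# ---------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    region_filter: Region | None = None,
    pop_map: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped (the count is logged).
    ``./.`` becomes :data:`MISSING`; phased and unphased separators are
    treated identically.  Population labels default to ``"pop0"`` unless a
    sample->population mapping is supplied.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as e:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"cannot parse VCF {path}: {e}") from e
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"VCF {path} declares no samples")

    dosage_rows, chroms, poss, refs, alts = [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if (
            len(rec.ALT) != 1
            or rec.REF not in _BASES
            or rec.ALT[0] not in _BASES
        ):
            n_skipped += 1
            continue
        if region_filter is not None and not region_filter.contains(
            rec.CHROM, rec.POS
        ):
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        row = np.empty(len(samples), dtype=np.int8)
        row[gt == 0] = 0
        row[gt == 1] = 1
        row[gt == 3] = 2
        row[gt == 2] = MISSING
        dosage_rows.append(row)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if not dosage_rows:
        raise EmptyInputError(f"no biallelic SNP records in {path}")

    pops = (
        [pop_map[s] for s in samples]
        if pop_map is not None
        else ["pop0"] * len(samples)
    )
    return GenotypeMatrix(
        dosages=np.stack(dosage_rows, axis=1),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        sample_ids=np.array(samples, dtype=object),
        pop_of_sample=np.array(pops, dtype=object),
    )


_GT_OF_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT-only FORMAT) for ``g``.

    ``read_vcf(write_vcf(g))`` is the identity on dosages, coordinates,
    alleles and sample ids.
    """
    if g.n_samples == 0:
        raise ValueError("cannot write a VCF with an empty sample list")
    g.validate()  # refuses unsorted coordinates
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(g.chrom):
            length = int(g.pos[g.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.sample_ids))
            + "\n"
        )
        for j in range(g.n_snps):
            gts = "\t".join(_GT_OF_DOSAGE[int(d)] for d in g.dosages[:, j])
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t.\t{g.ref_allele[j]}\t"
                f"{g.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------

def read_pop_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample, population) into a mapping."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            sample, pop = parts
            if sample in mapping:
                raise FormatError(f"{path}:{ln}: duplicate sample {sample!r}")
            mapping[sample] = pop
    if not mapping:
        raise EmptyInputError(f"empty population map {path}")
    return mapping


def write_pop_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sample, pop in mapping.items():
            fh.write(f"{sample}\t{pop}\n")


def _read_env_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise FormatError(f"{path}: missing required 'site_id' column")
    df = df.set_index("site_id")
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise FormatError(f"{path}: non-numeric columns {bad}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values present")
    return df


def read_env_table(
    path_current: str | Path,
    paths_future: Mapping[str, str | Path] | None = None,
) -> EnvTable:
    """Read the current-scenario env CSV plus optional future scenario CSVs.

    Future layers are re-ordered (sites and variables) to match the current
    layer, so a permuted future file yields an identical table.
    """
    cur = _read_env_csv(path_current)
    values = {"current": cur.to_numpy(dtype=float)}
    for scen, p in (paths_future or {}).items():
        fut = _read_env_csv(p)
        if set(fut.index) != set(cur.index):
            raise FormatError(
                f"scenario {scen!r}: sites {sorted(set(fut.index) ^ set(cur.index))} "
                "do not match the current layer"
            )
        if set(fut.columns) != set(cur.columns):
            raise FormatError(f"scenario {scen!r}: variable columns differ")
        values[scen] = fut.loc[cur.index, cur.columns].to_numpy(dtype=float)
    return EnvTable(
        site_ids=list(cur.index), variables=list(cur.columns), values=values
    )


def write_env_table(env: EnvTable, prefix: str | Path) -> dict[str, Path]:
    """Write one ``<prefix>.<scenario>.csv`` per scenario; returns the paths."""
    out: dict[str, Path] = {}
    for scen in env.scenarios:
        p = Path(f"{prefix}.{scen}.csv")
        env.layer(scen).rename_axis("site_id").to_csv(p)
        out[scen] = p
    return out


def write_regions(regions: Iterable[Region], path: str | Path) -> None:
    """Write regions as BED3+score (0-based, half-open)."""
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.score:.6g}\n")


def read_regions(path: str | Path) -> list[Region]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            score = float(parts[3]) if len(parts) > 3 else 0.0
            out.append(Region(parts[0], int(parts[1]), int(parts[2]), score))
    return out
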