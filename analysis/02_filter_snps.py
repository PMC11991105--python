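"""Apply the study's SNP filters to the synthetic cohort.

Missingness > 0.1 and MAF < 0.05 removal, then windowed LD pruning
(50-SNP windows, step 10, r^2 > 0.1, the PLINK indep-pairwise convention)
ahead of the downstream scans.  Reads results/cohort/, writes
results/filtered/.
"""

from pathlib import Path

import pandas as pd

from islandadapt import FilterConfig, filter_missing_maf, ld_prune
from islandadapt.io_formats import read_pop_map, read_vcf, write_vcf

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "filtered"
    out.mkdir(parents=True, exist_ok=True)
    pop_map = read_pop_map(ROOT / "cohort" / "popmap.tsv")
    g = read_vcf(ROOT / "cohort" / "cohort.vcf", pop_map=pop_map)

    cfg = FilterConfig()
    g1, report = filter_missing_maf(g, cfg)
    g2, pruned = ld_prune(g1, cfg)
    write_vcf(g2, out / "filtered.vcf")
    pd.DataFrame(
        {
            "step": ["input", "missingness_removed", "maf_removed",
                     "ld_pruned", "kept"],
            "n_snps": [report.n_input, report.n_removed_missing,
                       report.n_removed_maf, len(pruned), g2.n_snps],
        }
    ).to_csv(out / "filter_report.tsv", sep="\t", index=False)

    print(f"input SNPs:            {report.n_input}")
    print(f"removed (missingness): {report.n_removed_missing}")
    print(f"removed (MAF < 0.05):  {report.n_removed_maf}")
    print(f"removed (LD r2 > 0.1): {len(pruned)}")
    print(f"retained:              {g2.n_snps}")


if __name__ == "__main__":
    main()
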