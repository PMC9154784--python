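"""Differential expression for the four recipient/donor contrasts.

NB-Wald tests with median-of-ratios normalization and trend-shrunk
dispersions; writes one result table per contrast and prints the DEG counts
(padj < 0.05) with their up/down split.
"""

from pathlib import Path

from fmtx import de
from fmtx.io import read_count_table, read_metadata

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = read_count_table(ROOT / "data" / "gene_counts.tsv")
    meta = read_metadata(ROOT / "data" / "metadata.tsv")
    contrasts = de.run_contrasts(counts, meta)
    for label, res in contrasts.items():
        res.to_csv(ROOT / f"de_{label}.tsv", sep="\t")
        hit = res[res["padj"] < 0.05]
        print(f"{label}: {len(hit)} DEGs "
              f"({int((hit['log2FC'] > 0).sum())} up, "
              f"{int((hit['log2FC'] < 0).sum())} down) of {len(res)} tested")


if __name__ == "__main__":
    main()
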