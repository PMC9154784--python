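"""Generate the default synthetic reciprocal-FMT cohort.

Writes the 16S ASV table, taxonomy, sample metadata, gene-count table,
interaction edge list and the ground-truth manifest under results/data/.
Every downstream driver reads from there, so re-running this script with a
different seed re-runs the whole analysis on a fresh cohort.
"""

import sys
from pathlib import Path

from fmtx import synthio
from fmtx.io import write_count_table, write_metadata, write_taxonomy

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synthio.SimulationConfig(seed=seed)
    data = synthio.simulate_dataset(cfg)
    write_count_table(data.asv_counts, OUT / "asv_counts.tsv")
    write_taxonomy(data.taxonomy, OUT / "taxonomy.tsv")
    write_metadata(data.asv_meta, OUT / "metadata.tsv")
    write_count_table(data.gene_counts, OUT / "gene_counts.tsv")
    data.edges.to_csv(OUT / "edges.tsv", sep="\t", index=False)
    data.truth.to_json(OUT / "truth.json")

    n_shifted = sum(1 for v in data.truth.genotype_taxa.values() if v != "none")
    print(f"cohort: 4 groups x {cfg.n_per_group} mice, seed {seed}")
    print(f"  {cfg.n_taxa} taxa ({n_shifted} genotype-specific), "
          f"{cfg.n_genes} genes ({cfg.n_opposite_genes} opposite-direction, "
          f"{cfg.n_same_sign_genes} same-sign confounders)")
    print(f"  {len(data.truth.planted_edges)} planted gene-taxon links "
          f"({sum(e['spurious'] for e in data.truth.planted_edges)} sign-inconsistent), "
          f"{len(data.truth.planted_modules)} interaction modules")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
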