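"""Profile the 16S side: diversity, normalization, ordination, biomarkers.

Reads results/data/, writes diversity/differential-abundance/ordination
tables under results/, and prints how much community variation genotype and
FMT treatment explain.
"""

from pathlib import Path

import pandas as pd

from fmtx import profile
from fmtx.io import read_count_table, read_metadata, read_taxonomy

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    counts = read_count_table(ROOT / "data" / "asv_counts.tsv")
    taxonomy = read_taxonomy(ROOT / "data" / "taxonomy.tsv")
    meta = read_metadata(ROOT / "data" / "metadata.tsv")

    alpha = profile.alpha_diversity(counts)
    alpha.to_csv(ROOT / "alpha_diversity.tsv", sep="\t")
    by_group = alpha.join(meta["group"]).groupby("group")["shannon"].mean()
    print("mean Shannon H by group:")
    print(by_group.round(3).to_string())

    genus = profile.collapse_genus(counts, taxonomy)
    css = profile.css_normalize(genus)
    css.normalized.to_csv(ROOT / "genus_css.tsv", sep="\t")
    print(f"\n{genus.data.shape[0]} genus-level lineages, "
          f"CSS quantile {css.quantile:.2f}")

    dist = profile.bray_curtis(css.normalized)
    perm = profile.permanova(dist, meta, ["genotype", "treatment"], seed=seed)
    perm.to_csv(ROOT / "permanova.tsv", sep="\t")
    rda = profile.rda_constrained(css.normalized, meta,
                                  ["genotype", "treatment"], seed=seed)
    print("\nPERMANOVA (Bray-Curtis) and RDA variance partitioning:")
    for factor in ("genotype", "treatment"):
        print(f"  {factor}: PERMANOVA R2 = {perm.loc[factor, 'R2']:.1%} "
              f"(p = {perm.loc[factor, 'p_perm']:.3f}); "
              f"RDA fraction = {rda.constrained_variance_fractions[factor]:.1%} "
              f"(p = {rda.p_perm[factor]:.3f})")

    clades = profile.expand_ranks(counts, taxonomy)
    for genotype in ("WT", "KO"):
        meta_g = meta[meta["genotype"] == genotype]
        da = profile.diff_abundance_paired(css.normalized, meta, genotype=genotype)
        da.to_csv(ROOT / f"diffabund_{genotype}.tsv", sep="\t")
        lef = profile.lefse_lite(clades[list(meta_g.index)], meta_g,
                                 "treatment", seed=seed)
        lef.to_csv(ROOT / f"lefse_{genotype}.tsv", sep="\t")
        n_da = int((da["padj"] < 0.05).sum())
        print(f"\n{genotype}: {n_da} genera shift upon FMT (paired Wilcoxon, "
              f"padj < 0.05); {int(lef['passes'].sum())} clades pass the "
              f"LDA-effect-size screen")


if __name__ == "__main__":
    main()
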