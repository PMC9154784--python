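"""Correlate signature-gene expression with taxon abundance and build the
mixed gene-taxon network.

Per genotype, Pearson correlations between log2 normalized expression of the
FMT-responsive genes and log2 CSS ASV abundances across that genotype's FMT
mice; BH over all pairs; candidates screened by the fold-change
sign-consistency rule.  Prints precision/recall against the planted links and
the fraction of signature genes with at least one taxon partner.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fmtx import de, integration, profile, signature as sig
from fmtx.io import read_count_table, read_metadata, read_edge_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gene_counts = read_count_table(ROOT / "data" / "gene_counts.tsv")
    asv_counts = read_count_table(ROOT / "data" / "asv_counts.tsv")
    meta = read_metadata(ROOT / "data" / "metadata.tsv")
    signature = pd.read_csv(ROOT / "signature.tsv", sep="\t", index_col=0)

    sf = de.size_factors(gene_counts)
    expr = np.log2(gene_counts.data / sf + 1.0)
    css = profile.css_normalize(asv_counts)
    taxa_log = np.log2(css.normalized + 1.0)

    frames = []
    for genotype, label in (("WT", "WT_vs_WTFMT"), ("KO", "KO_vs_KOFMT")):
        contrast = pd.read_csv(ROOT / f"de_{label}.tsv", sep="\t", index_col=0)
        responsive = contrast.index[contrast["padj"] < 0.05]
        diffabund = profile.diff_abundance_paired(css.normalized, meta,
                                                  genotype=genotype)
        cand = integration.correlate_gene_taxon(
            expr.loc[responsive], taxa_log, meta, genotype)
        kept = integration.sign_consistency_filter(
            cand, gene_lfc=contrast["log2FC"],
            taxon_lfc=diffabund["median_lfc_proxy"],
            opposite_genes=signature.index)
        frames.append(kept)
        print(f"{genotype}: {len(kept)} pairs, "
              f"{int(kept['candidate'].sum())} candidates (padj < 0.05), "
              f"{int(kept['kept'].sum())} sign-consistent kept")
    corr = pd.concat(frames, ignore_index=True)
    corr.to_csv(ROOT / "correlations.tsv", sep="\t", index=False)

    truth = json.loads((ROOT / "data" / "truth.json").read_text())
    planted = pd.DataFrame(truth["planted_edges"])
    kept_pairs = set(map(tuple, corr.loc[corr["kept"], ["gene_id", "taxon_id"]].values))
    true_pairs = set(map(tuple, planted.loc[~planted["spurious"], ["gene", "taxon"]].values))
    spur_pairs = set(map(tuple, planted.loc[planted["spurious"], ["gene", "taxon"]].values))
    tp = kept_pairs & true_pairs
    print(f"\nplanted-link recovery: precision "
          f"{len(tp) / max(len(kept_pairs), 1):.2f}, "
          f"recall {len(tp) / len(true_pairs):.2f}; "
          f"{len(kept_pairs & spur_pairs)} of {len(spur_pairs)} "
          f"sign-inconsistent links survived (should be 0)")

    gene_net = sig.build_network(signature.index,
                                 read_edge_table(ROOT / "data" / "edges.tsv"))
    mixed = integration.assemble_mixed_network(corr, gene_net,
                                                signature_genes=signature.index)
    print(f"mixed network: {len(mixed.gene_nodes)} genes, "
          f"{len(mixed.taxon_nodes)} taxa; "
          f"{mixed.taxon_linked_fraction:.0%} of signature genes have >= 1 "
          f"taxon partner")


if __name__ == "__main__":
    main()
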