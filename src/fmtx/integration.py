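"""Gene-taxon correlation network with sign-consistency filtering.

Within one genotype's FMT samples, every (gene, taxon) pair gets a Pearson
correlation between log2 normalized expression and log2 CSS taxon abundance,
with a two-sided t-based p and BH adjustment over all pairs of the genotype.
Because donor/control samples are unpaired with the recipients, candidate
correlations (padj < 0.05) are then screened by fold-change signs: a positive
correlation must pair gene and taxon fold-changes of equal sign, a negative
correlation fold-changes of opposite sign; candidates from genes outside the
opposite-direction signature (|lfc| > threshold) are likewise discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError
from .profile import bh_adjust

logger = logging.getLogger(__name__)


def correlate_gene_taxon(expression: pd.DataFrame, taxon_abundance: pd.DataFrame,
                         meta: pd.DataFrame, genotype: str,
                         padj_threshold: float = 0.05) -> pd.DataFrame:
    """All-pairs Pearson correlations within one genotype's FMT samples.

    ``expression``: genes x samples normalized (log) expression, already
    restricted to the genes of interest (significant FMT responders).
    ``taxon_abundance``: taxa x samples normalized abundances.  Pairs where
    either vector has zero variance are skipped with a log entry.  Returns all
    pairs with r, p, padj and a ``candidate`` flag (padj < threshold).
    """
    meta = meta[(meta["genotype"] == genotype) & (meta["treatment"] == "FMT")]
    samples = [s for s in meta.index if s in expression.columns and s in taxon_abundance.columns]
    if len(samples) < 4:
        raise ValidationError(f"genotype {genotype!r}: fewer than 4 shared FMT samples")
    x = expression[samples].to_numpy(dtype=float)
    y = taxon_abundance[samples].to_numpy(dtype=float)
    n = len(samples)
    sx = x.std(axis=1)
    sy = y.std(axis=1)
    ok_g = sx > 0
    ok_t = sy > 0
    for ids, ok, what in ((expression.index, ok_g, "gene"), (taxon_abundance.index, ok_t, "taxon")):
        if (~ok).any():
            logger.info("skipping %d zero-variance %s(s)", int((~ok).sum()), what)
    zx = (x - x.mean(axis=1, keepdims=True)) / np.where(sx > 0, sx, 1.0)[:, None]
    zy = (y - y.mean(axis=1, keepdims=True)) / np.where(sy > 0, sy, 1.0)[:, None]
    r = zx @ zy.T / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    mask = np.outer(ok_g, ok_t)
    gi, ti = np.where(mask)
    out = pd.DataFrame({
        "gene_id": np.asarray(expression.index)[gi],
        "taxon_id": np.asarray(taxon_abundance.index)[ti],
        "genotype": genotype,
        "r": r[gi, ti],
        "p": p[gi, ti],
    })
    out["padj"] = bh_adjust(out["p"])
    out["candidate"] = out["padj"] < padj_threshold
    return out


def sign_consistency_filter(candidates: pd.DataFrame, gene_lfc: pd.Series,
                            taxon_lfc: pd.Series, lfc_threshold: float = 0.58,
                            opposite_genes=None) -> pd.DataFrame:
    """Pure sign-consistency predicate over candidate correlation edges.

    A candidate is kept iff padj < 0.05 already held (``candidate``), the sign
    rule holds — r > 0 with equal fold-change signs, or r < 0 with opposite
    signs — and the gene belongs to the opposite-direction set with
    |gene lfc| > threshold.  Edges with a missing fold-change are dropped with
    an NA verdict and a log entry.
    """
    out = candidates.copy()
    glfc = out["gene_id"].map(gene_lfc)
    tlfc = out["taxon_id"].map(taxon_lfc)
    out["gene_lfc"] = glfc
    out["taxon_lfc"] = tlfc
    missing = glfc.isna() | tlfc.isna()
    if missing.any():
        logger.info("%d candidate edge(s) miss a fold-change; verdict NA", int(missing.sum()))
    prod = glfc * tlfc
    consistent = ((out["r"] > 0) & (prod > 0)) | ((out["r"] < 0) & (prod < 0))
    out["sign_consistent"] = consistent.where(~missing, other=np.nan)
    in_opposite = (
        out["gene_id"].isin(set(opposite_genes)) if opposite_genes is not None else True
    )
    kept = out["candidate"] & consistent & (glfc.abs() > lfc_threshold) & in_opposite
    out["kept"] = kept.where(~missing, other=False).astype(bool)
    return out


@dataclass
class MixedNetwork:
    graph: nx.Graph
    gene_nodes: list
    taxon_nodes: list
    #: fraction of signature genes with at least one taxon edge
    taxon_linked_fraction: float


def assemble_mixed_network(kept_edges: pd.DataFrame, gene_network: nx.Graph,
                           signature_genes=None) -> MixedNetwork:
    """Union of the kept gene-taxon correlation edges (solid, bipartite) and
    the gene-gene interaction edges (dotted); reports the fraction of
    signature genes associated with at least one taxon."""
    g = nx.Graph()
    for node in gene_network.nodes:
        g.add_node(node, kind="gene")
    for u, v, data in gene_network.edges(data=True):
        g.add_edge(u, v, kind="interaction", weight=data.get("weight", 1.0))
    kept = kept_edges[kept_edges["kept"]] if "kept" in kept_edges else kept_edges
    for row in kept.itertuples(index=False):
        g.add_node(row.gene_id, kind="gene")
        g.add_node(row.taxon_id, kind="taxon")
        g.add_edge(row.gene_id, row.taxon_id, kind="correlation",
                   weight=float(row.r), genotype=row.genotype)
    genes = sorted(n for n, d in g.nodes(data=True) if d["kind"] == "gene")
    taxa = sorted(n for n, d in g.nodes(data=True) if d["kind"] == "taxon")
    pool = list(signature_genes) if signature_genes is not None else genes
    if pool:
        linked = sum(
            1 for gene in pool
            if gene in g and any(g.nodes[v]["kind"] == "taxon" for v in g[gene])
        )
        fraction = linked / len(pool)
    else:
        fraction = 0.0
    return MixedNetwork(graph=g, gene_nodes=genes, taxon_nodes=taxa,
                        taxon_linked_fraction=fraction)
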