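"""Opposite-direction core gene signature and its interaction network.

A gene enters the signature when it is significantly differentially expressed
in BOTH recipient-vs-donor contrasts (padj below threshold), with |log2FC|
strictly above the threshold in both, and with fold-changes of OPPOSITE sign
— the pattern expected of genes tracking the transplanted microbiota rather
than the transplant procedure.  Signature genes are classified as "restored"
when they show no significant difference from the opposite genotype's control
in the cross-genotype comparisons.  The induced interaction network keeps
edges with confidence strictly above the score threshold and deletes
components smaller than three nodes; cohesive clusters are found by a greedy
seeded growth of the cohesiveness objective

    f(V) = W_in(V) / (W_in(V) + W_bound(V) + penalty * |V|)

with overlapping candidates merged at match coefficient >= 0.8 and a one-sided
Mann-Whitney p comparing in-cluster versus boundary edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SignatureConfig:
    lfc_threshold: float = 0.58
    padj_threshold: float = 0.05
    score_threshold: float = 0.4
    min_cluster_size: int = 3
    cohesiveness_penalty: float = 2.0
    cluster_p_threshold: float = 0.05

    def validate(self) -> None:
        for name in ("lfc_threshold", "padj_threshold", "score_threshold",
                     "cohesiveness_penalty", "cluster_p_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


def extract_opposite_signature(contrast_a: pd.DataFrame, contrast_b: pd.DataFrame,
                               cfg: SignatureConfig | None = None) -> pd.DataFrame:
    """Genes opposite-significant in both contrasts (strict |lfc| threshold).

    ``contrast_a``/``contrast_b`` are gene-indexed frames with log2FC and padj
    (the two recipient-vs-donor comparisons).  Returns a gene-indexed frame
    with lfc_A, lfc_B, padj_A, padj_B; the ``restored`` column is added by
    :func:`classify_restoration`.
    """
    cfg = cfg or SignatureConfig()
    cfg.validate()
    shared = contrast_a.index.intersection(contrast_b.index)
    if len(shared) == 0:
        raise ValidationError("contrasts share no genes")
    a = contrast_a.loc[shared]
    b = contrast_b.loc[shared]
    t, tau = cfg.padj_threshold, cfg.lfc_threshold
    keep = (
        (a["padj"] < t) & (b["padj"] < t)
        & (a["log2FC"].abs() > tau) & (b["log2FC"].abs() > tau)
        & (a["log2FC"] * b["log2FC"] < 0)
    )
    keep = keep.fillna(False)
    out = pd.DataFrame({
        "lfc_A": a["log2FC"][keep], "lfc_B": b["log2FC"][keep],
        "padj_A": a["padj"][keep], "padj_B": b["padj"][keep],
    })
    out.index.name = "gene_id"
    return out.sort_index()


def classify_restoration(signature: pd.DataFrame, cross_a: pd.DataFrame,
                         cross_b: pd.DataFrame, padj_threshold: float = 0.05) -> pd.DataFrame:
    """Flag signature genes restored to the opposite genotype's baseline.

    A gene is restored when its padj is >= threshold (no remaining significant
    difference) in BOTH cross-genotype comparisons; genes missing from a cross
    contrast get NA and a log entry.
    """
    out = signature.copy()
    restored = []
    for g in out.index:
        vals = []
        for cross in (cross_a, cross_b):
            if g in cross.index:
                vals.append(cross.loc[g, "padj"])
        if len(vals) < 2:
            logger.info("gene %s missing from a cross contrast; restored = NA", g)
            restored.append(np.nan)
            continue
        restored.append(bool(all(not (v < padj_threshold) for v in vals)))
    out["restored"] = restored
    return out


def build_network(signature_genes, edges: pd.DataFrame,
                  cfg: SignatureConfig | None = None) -> nx.Graph:
    """Induced interaction subgraph on the signature genes.

    Keeps edges with score strictly greater than the threshold, drops
    self-loops, then deletes connected components with fewer than 3 nodes
    (single nodes and two-node clusters).  An empty network is allowed.
    """
    cfg = cfg or SignatureConfig()
    if ((edges["score"] < 0) | (edges["score"] > 1)).any():
        raise ValidationError("edge scores must lie in [0, 1]")
    genes = set(signature_genes)
    g = nx.Graph()
    g.add_nodes_from(sorted(genes))
    for a, b, score in edges[["gene_a", "gene_b", "score"]].itertuples(index=False):
        if a == b or a not in genes or b not in genes:
            continue
        if score > cfg.score_threshold:
            g.add_edge(a, b, weight=float(score))
    for comp in list(nx.connected_components(g)):
        if len(comp) < 3:
            g.remove_nodes_from(comp)
    return g


@dataclass
class ClusterResult:
    members: list = field(default_factory=list)
    cohesiveness: float = 0.0
    p: float = float("nan")
    significant: bool = False


def _cohesiveness(g: nx.Graph, members: set, penalty: float) -> float:
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        for v, data in g[u].items():
            if v in members:
                w_in += data["weight"]
            else:
                w_bound += data["weight"]
    w_in /= 2.0
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def _grow_from_seed(g: nx.Graph, seed_set, penalty: float) -> frozenset:
    """Best-improvement hill climbing with grow, shrink and swap moves.

    Swaps (replace one member by one boundary node) are only tried when no
    single add/remove improves; they let the search slide off plateaus that
    single-node moves cannot leave.
    """
    members = set(seed_set)
    f = _cohesiveness(g, members, penalty)
    while True:
        best_f, best_set = f, None
        boundary = {v for u in members for v in g[u] if v not in members}
        for v in boundary:
            cand = members | {v}
            fc = _cohesiveness(g, cand, penalty)
            if fc > best_f + 1e-12:
                best_f, best_set = fc, cand
        if len(members) > 1:
            for v in members:
                cand = members - {v}
                fc = _cohesiveness(g, cand, penalty)
                if fc > best_f + 1e-12:
                    best_f, best_set = fc, cand
        if best_set is None:
            for v_in in list(members):
                for v_out in boundary:
                    cand = (members - {v_in}) | {v_out}
                    fc = _cohesiveness(g, cand, penalty)
                    if fc > best_f + 1e-12:
                        best_f, best_set = fc, cand
        if best_set is None:
            return frozenset(members)
        members, f = set(best_set), best_f


def _match_coefficient(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def clusterone_clusters(g: nx.Graph, cfg: SignatureConfig | None = None) -> list[ClusterResult]:
    """Greedy cohesive clusters with significance.

    Growth is seeded from every node in decreasing weighted-degree order;
    converged candidates overlapping at match coefficient >= 0.8 are merged;
    clusters below the minimum size are dropped.  p per cluster is a one-sided
    Mann-Whitney U comparing in-cluster against boundary edge weights (a
    cluster with no boundary edges gets p = 0, maximal separation).
    """
    cfg = cfg or SignatureConfig()
    cfg.validate()
    if g.number_of_nodes() == 0:
        return []
    penalty = cfg.cohesiveness_penalty
    order = sorted(g.nodes, key=lambda n: (-g.degree(n, weight="weight"), str(n)))
    # seeds: every node (decreasing weighted degree), every edge, and every
    # connected component (the last lets shrink moves find large optima)
    seeds: list[set] = [{n} for n in order]
    seeds += [{u, v} for u, v in sorted(g.edges, key=lambda e: (str(e[0]), str(e[1])))]
    seeds += [set(c) for c in nx.connected_components(g)]
    candidates: list[frozenset] = []
    for seed in seeds:
        grown = _grow_from_seed(g, seed, penalty)
        if grown not in candidates:
            candidates.append(grown)
    # merge overlapping candidates (match coefficient >= 0.8) until stable
    merged = True
    while merged:
        merged = False
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                if _match_coefficient(candidates[i], candidates[j]) >= 0.8:
                    union = candidates[i] | candidates[j]
                    candidates = [c for k, c in enumerate(candidates) if k not in (i, j)]
                    if union not in candidates:
                        candidates.append(union)
                    merged = True
                    break
            if merged:
                break
    results = []
    for cand in candidates:
        if len(cand) < cfg.min_cluster_size:
            continue
        in_w, bound_w = [], []
        for u in cand:
            for v, data in g[u].items():
                if v in cand:
                    if str(u) < str(v):
                        in_w.append(data["weight"])
                else:
                    bound_w.append(data["weight"])
        if not in_w:
            continue
        if not bound_w:
            p = 0.0
        else:
            p = float(stats.mannwhitneyu(in_w, bound_w, alternative="greater").pvalue)
        results.append(ClusterResult(
            members=sorted(cand),
            cohesiveness=_cohesiveness(g, set(cand), penalty),
            p=p,
            significant=bool(p < cfg.cluster_p_threshold),
        ))
    results.sort(key=lambda c: (-c.cohesiveness, c.members))
    return results


def clusters_to_frame(clusters: list[ClusterResult]) -> pd.DataFrame:
    rows = [
        {"cluster_id": i + 1, "n_members": len(c.members),
         "genes": ",".join(map(str, c.members)), "cohesiveness": c.cohesiveness,
         "p": c.p, "significant": c.significant}
        for i, c in enumerate(clusters)
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "n_members", "genes",
                                       "cohesiveness", "p", "significant"]).set_index("cluster_id")
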