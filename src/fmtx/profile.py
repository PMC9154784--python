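"""Community profiling: alpha diversity, genus collapsing, cumulative sum
scaling, paired differential abundance, LDA-effect-size biomarker scan,
distance-based PERMANOVA and constrained ordination (RDA).

Conventions (recorded in output metadata where relevant): Shannon entropy in
natural log; Chao1 in the bias-corrected form observed + F1(F1-1)/(2(F2+1)),
which stays defined when no doubletons are seen; pseudocount 1 before any log
ratio; Bray-Curtis as the default community distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io import CountTable, RANKS, ValidationError

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(counts: CountTable) -> pd.DataFrame:
    """Per-sample richness/diversity on raw (unrarefied) counts.

    Returns a DataFrame indexed by sample with columns observed, F1, F2,
    chao1, shannon (natural log) and inv_simpson.
    """
    rows = {}
    for s in counts.sample_ids:
        x = counts.data[s].to_numpy()
        total = x.sum()
        if total == 0:
            raise ValidationError(f"sample {s!r} has zero total count")
        observed = int((x > 0).sum())
        f1 = int((x == 1).sum())
        f2 = int((x == 2).sum())
        chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        p = x[x > 0] / total
        shannon = float(-(p * np.log(p)).sum())
        inv_simpson = float(1.0 / (p ** 2).sum())
        rows[s] = dict(observed=observed, F1=f1, F2=f2, chao1=chao1,
                       shannon=shannon, inv_simpson=inv_simpson)
    out = pd.DataFrame(rows).T
    out.index.name = "sample"
    out.attrs["shannon_log_base"] = "e"
    return out


# ---------------------------------------------------------------------------
# genus collapsing
# ---------------------------------------------------------------------------

def collapse_genus(counts: CountTable, taxonomy: pd.DataFrame) -> CountTable:
    """Sum ASV rows sharing an identical Phylum..Genus lineage.

    ASVs with no genus assignment are grouped by their finest assigned rank
    under an ``unclassified_<finest label>`` genus, so column sums are always
    conserved exactly.
    """
    missing = [a for a in counts.feature_ids if a not in taxonomy.index]
    if missing:
        raise ValidationError(f"taxonomy misses ASV {missing[0]!r}")
    keys = []
    upper = [r for r in RANKS if r not in ("Genus", "Species")]
    for asv in counts.feature_ids:
        row = taxonomy.loc[asv]
        lineage = [str(row.get(r, "") or "") for r in upper]
        genus = str(row.get("Genus", "") or "")
        if not genus:
            assigned = [v for v in lineage if v]
            finest = assigned[-1] if assigned else "root"
            genus = f"unclassified_{finest}"
        keys.append(";".join(lineage + [genus]))
    collapsed = counts.data.groupby(pd.Index(keys, name="lineage"), sort=True).sum()
    return CountTable(collapsed)


# ---------------------------------------------------------------------------
# cumulative sum scaling
# ---------------------------------------------------------------------------

def _adaptive_css_quantile(matrix: np.ndarray) -> float:
    """Instability rule of the cumulative-sum-scaling method: scan quantile
    levels of each sample's nonzero counts and pick the smallest level where
    the median deviation from the across-sample reference changes by more than
    10% relative; fall back to 0.5 when the rule is undefined (tiny tables)."""
    levels = np.arange(0.05, 0.991, 0.01)
    cols = []
    for j in range(matrix.shape[1]):
        nz = np.sort(matrix[:, j][matrix[:, j] > 0])
        if nz.size < 2:
            return 0.5
        cols.append(np.quantile(nz, levels))
    q = np.column_stack(cols)
    ref = q.mean(axis=1, keepdims=True)
    d = np.median(np.abs(q - ref), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(np.diff(d)) / np.where(d[:-1] > 0, d[:-1], np.nan)
    hits = np.where(rel > 0.1)[0]
    if hits.size == 0:
        return 0.5
    # the reference method floors the instability point at the median
    return float(max(levels[hits[0]], 0.5))


@dataclass
class CssResult:
    normalized: pd.DataFrame
    scaling_factors: pd.Series
    quantile: float
    log2: bool


def css_normalize(counts: CountTable, quantile: float | str = "auto",
                  log2: bool = False) -> CssResult:
    """Cumulative sum scaling: divide each sample by the sum of its counts at
    or below the chosen quantile of its nonzero counts, times 1000.

    ``quantile='auto'`` applies the adaptive instability rule; a float fixes
    the level.  ``log2=True`` applies log2(x + 1) after scaling.
    """
    mat = counts.data.to_numpy().astype(float)
    nnz = (mat > 0).sum(axis=0)
    if (nnz < 2).any():
        bad = counts.sample_ids[int(np.argmax(nnz < 2))]
        raise ValidationError(f"sample {bad!r} has fewer than 2 nonzero features")
    q = _adaptive_css_quantile(mat) if quantile == "auto" else float(quantile)
    factors = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        nz = mat[:, j][mat[:, j] > 0]
        qval = np.quantile(nz, q)
        factors[j] = mat[:, j][mat[:, j] <= qval].sum()
    norm = mat / factors[None, :] * 1000.0
    if log2:
        norm = np.log2(norm + 1.0)
    return CssResult(
        normalized=pd.DataFrame(norm, index=counts.feature_ids, columns=counts.sample_ids),
        scaling_factors=pd.Series(factors, index=counts.sample_ids, name="css_factor"),
        quantile=q,
        log2=log2,
    )


# ---------------------------------------------------------------------------
# paired differential abundance
# ---------------------------------------------------------------------------

def diff_abundance_paired(abundance: pd.DataFrame, meta: pd.DataFrame,
                          grouping: tuple[str, str] = ("control", "FMT"),
                          genotype: str | None = None) -> pd.DataFrame:
    """Two-sided paired Wilcoxon signed-rank per taxon on (CSS-normalized)
    abundances, pre vs post FMT, BH-adjusted across taxa.

    ``abundance`` is taxa x samples; pairing uses the metadata ``pair_id``.
    Zero-difference pairs are dropped (classical procedure); taxa with fewer
    than 3 informative pairs get NA.  ``median_lfc_proxy`` is the median
    paired log2 ratio with pseudocount 1.
    """
    meta = meta.loc[[s for s in abundance.columns if s in meta.index]]
    if genotype is not None:
        meta = meta[meta["genotype"] == genotype]
    pre, post = grouping
    m_pre = meta[meta["treatment"] == pre]
    m_post = meta[meta["treatment"] == post]
    pairs = sorted(set(m_pre["pair_id"]) & set(m_post["pair_id"]))
    if not pairs:
        raise ValidationError("no complete pre/post pairs found")
    pre_ids = m_pre.reset_index().set_index("pair_id").loc[pairs, "sample"]
    post_ids = m_post.reset_index().set_index("pair_id").loc[pairs, "sample"]
    a = abundance[list(pre_ids)].to_numpy()
    b = abundance[list(post_ids)].to_numpy()
    rows = []
    for i, taxon in enumerate(abundance.index):
        diff = b[i] - a[i]
        lfc = float(np.median(np.log2((b[i] + 1.0) / (a[i] + 1.0))))
        informative = diff[diff != 0]
        if informative.size < 3:
            rows.append((taxon, lfc, np.nan, np.nan))
            logger.info("taxon %s skipped: %d informative pair(s)", taxon, informative.size)
            continue
        method = "exact" if informative.size <= 25 else "approx"
        res = stats.wilcoxon(informative, zero_method="wilcox",
                             alternative="two-sided", method=method)
        rows.append((taxon, lfc, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["taxon", "median_lfc_proxy", "statistic", "p"])
    out["padj"] = bh_adjust(out["p"])
    return out.set_index("taxon")


# ---------------------------------------------------------------------------
# LDA effect size scan
# ---------------------------------------------------------------------------

def expand_ranks(counts: CountTable, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Stack clade abundances at every rank phylum..genus (per-mille of each
    sample's total), the clade table a cladogram-style biomarker scan runs on."""
    totals = counts.data.sum(axis=0).astype(float)
    blocks = []
    use_ranks = [r for r in RANKS if r not in ("Kingdom", "Species")]
    for depth, rank in enumerate(use_ranks, start=1):
        keys = []
        for asv in counts.feature_ids:
            row = taxonomy.loc[asv]
            lineage = [str(row.get(r, "") or "") for r in use_ranks[:depth]]
            if not lineage[-1]:
                keys.append(None)
            else:
                keys.append(f"{rank[0].lower()}__" + ";".join(lineage))
        mask = [k is not None for k in keys]
        sub = counts.data.loc[mask]
        grouped = sub.groupby(pd.Index([k for k in keys if k is not None]), sort=True).sum()
        blocks.append(grouped)
    clades = pd.concat(blocks)
    clades = clades[~clades.index.duplicated()]
    return clades / totals * 1000.0


def lefse_lite(clades: pd.DataFrame, meta: pd.DataFrame, class_col: str,
               alpha: float = 0.05, lda_threshold: float = 2.0,
               n_boot: int = 30, seed: int = 0) -> pd.DataFrame:
    """Two-class biomarker scan: Kruskal-Wallis gate at ``alpha``, then a
    bootstrapped one-dimensional linear-discriminant effect size, reported as
    log10 of the absolute between-class discriminant effect (per-mille scale).

    ``clades`` is the per-mille clade table from :func:`expand_ranks`.
    """
    meta = meta.loc[[s for s in clades.columns if s in meta.index]]
    classes = sorted(meta[class_col].unique())
    if len(classes) != 2:
        raise ValidationError(f"exactly 2 classes required, got {classes}")
    ids_a = list(meta.index[meta[class_col] == classes[0]])
    ids_b = list(meta.index[meta[class_col] == classes[1]])
    if min(len(ids_a), len(ids_b)) < 3:
        raise ValidationError("each class needs >= 3 samples")
    rng = np.random.default_rng(seed)
    rows = []
    for clade in clades.index:
        xa = clades.loc[clade, ids_a].to_numpy(dtype=float)
        xb = clades.loc[clade, ids_b].to_numpy(dtype=float)
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            kw_p = 1.0
        else:
            kw_p = float(stats.kruskal(xa, xb).pvalue)
        enriched = classes[0] if xa.mean() >= xb.mean() else classes[1]
        if kw_p >= alpha:
            rows.append((clade, enriched, kw_p, np.nan, False))
            continue
        effects = []
        for _ in range(n_boot):
            sa = rng.choice(xa, size=max(3, int(np.ceil(2 * len(xa) / 3))), replace=False) \
                if len(xa) >= 4 else xa
            sb = rng.choice(xb, size=max(3, int(np.ceil(2 * len(xb) / 3))), replace=False) \
                if len(xb) >= 4 else xb
            effects.append(abs(sa.mean() - sb.mean()))
        lda = float(np.log10(max(np.mean(effects), 1e-10)))
        rows.append((clade, enriched, kw_p, lda, bool(lda >= lda_threshold and kw_p < alpha)))
    return pd.DataFrame(
        rows, columns=["taxon", "enriched_class", "kw_p", "lda_score", "passes"]
    ).set_index("taxon")


# ---------------------------------------------------------------------------
# PERMANOVA (adonis-style, sequential sums of squares)
# ---------------------------------------------------------------------------

def bray_curtis(abundance: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distances between samples of a taxa x samples table."""
    d = squareform(pdist(abundance.to_numpy().T, metric="braycurtis"))
    return pd.DataFrame(d, index=abundance.columns, columns=abundance.columns)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _design_columns(meta: pd.DataFrame, factor: str) -> np.ndarray:
    levels = sorted(pd.unique(meta[factor]))
    if len(levels) < 2:
        raise ValidationError(f"factor {factor!r} has fewer than 2 levels")
    return np.column_stack([(meta[factor] == lv).to_numpy(float) for lv in levels[1:]])


def permanova(distance: pd.DataFrame, meta: pd.DataFrame, factors: list[str],
              n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Permutational multivariate ANOVA with sequential (type-I) partitioning
    of a Gower-centered distance matrix; p by free permutation of sample labels.

    Returns one row per factor: df, SS, pseudo_F, R2, p_perm, n_permutations.
    """
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    meta = meta.loc[list(distance.index)]
    n = d.shape[0]
    g = _gower_center(d)
    blocks = [np.ones((n, 1))]
    dfs = []
    for f in factors:
        cols = _design_columns(meta, f)
        blocks.append(cols)
        dfs.append(cols.shape[1])
    hats = []
    x = blocks[0]
    for b in blocks[1:]:
        x = np.column_stack([x, b])
        hats.append(_hat(x))
    ss_total = float(np.trace(g))
    df_res = n - 1 - sum(dfs)

    def stats_for(gmat):
        traces = [float(np.trace(h @ gmat)) for h in hats]
        ss = np.diff([0.0] + traces)
        ss_res = np.trace(gmat) - traces[-1]
        f_vals = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, f_vals

    ss_obs, f_obs = stats_for(g)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(factors))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, f_p = stats_for(g[np.ix_(perm, perm)])
        exceed += f_p >= f_obs - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    return pd.DataFrame({
        "factor": factors, "df": dfs, "SS": ss_obs, "pseudo_F": f_obs,
        "R2": ss_obs / ss_total, "p_perm": p, "n_permutations": n_perm,
    }).set_index("factor")


# ---------------------------------------------------------------------------
# constrained ordination (RDA)
# ---------------------------------------------------------------------------

@dataclass
class RdaResult:
    constrained_variance_fractions: dict
    p_perm: dict
    axis_scores: pd.DataFrame
    taxon_loadings: pd.DataFrame
    total_inertia: float
    constrained_inertia: float


def rda_constrained(abundance: pd.DataFrame, meta: pd.DataFrame,
                    constraints: list[str], n_perm: int = 999,
                    seed: int = 0) -> RdaResult:
    """Redundancy analysis of a (CSS-normalized) taxa x samples table on
    categorical constraints, with sequential variance partitioning and an
    ANOVA-like permutation test per factor.

    The response is the transposed, column-centered abundance matrix; the
    constrained axes are the SVD of the fitted values of the full model.
    """
    meta = meta.loc[list(abundance.columns)]
    y = abundance.to_numpy(dtype=float).T
    y = y - y.mean(axis=0, keepdims=True)
    n = y.shape[0]
    blocks, dfs = [np.ones((n, 1))], []
    for f in constraints:
        cols = _design_columns(meta, f)
        blocks.append(cols)
        dfs.append(cols.shape[1])
    x_full = np.column_stack(blocks)
    expected_rank = 1 + sum(dfs)
    if np.linalg.matrix_rank(x_full) < expected_rank:
        for k in range(1, len(blocks)):
            if np.linalg.matrix_rank(np.column_stack(blocks[: k + 1])) < 1 + sum(dfs[:k]):
                raise ValidationError(f"constraint {constraints[k - 1]!r} is aliased")
        raise ValidationError("collinear constraint design")
    total = float((y ** 2).sum())
    df_res = n - expected_rank

    def inertias(ymat):
        out, x = [], blocks[0]
        for b in blocks[1:]:
            x = np.column_stack([x, b])
            fitted = _hat(x) @ ymat
            out.append(float((fitted ** 2).sum()))
        return np.diff([0.0] + out)

    parts = inertias(y)
    constrained = float(parts.sum())
    resid = total - constrained
    f_obs = (parts / np.array(dfs)) / (resid / df_res)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(constraints))
    for _ in range(n_perm):
        yp = y[rng.permutation(n)]
        parts_p = inertias(yp)
        resid_p = total - parts_p.sum()
        f_p = (parts_p / np.array(dfs)) / (resid_p / df_res)
        exceed += f_p >= f_obs - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    fitted = _hat(x_full) @ y
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = int((s > 1e-9).sum())
    axes = [f"RDA{i + 1}" for i in range(n_axes)]
    return RdaResult(
        constrained_variance_fractions={f: float(v / total) for f, v in zip(constraints, parts)},
        p_perm={f: float(v) for f, v in zip(constraints, p)},
        axis_scores=pd.DataFrame((u * s)[:, :n_axes], index=abundance.columns, columns=axes),
        taxon_loadings=pd.DataFrame(vt[:n_axes].T, index=abundance.index, columns=axes),
        total_inertia=total,
        constrained_inertia=constrained,
    )
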