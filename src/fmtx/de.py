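"""Negative-binomial Wald differential expression for the four-group design.

The chain is: median-of-ratios size factors; per-gene method-of-moments
dispersion with a log-linear mean-dispersion trend and a weighted geometric
shrinkage of the raw estimate toward the trend; per-group NB GLM fits (log
link, cell-means parameterization, Newton scoring with the expected
information); Wald z on the log2 fold-change of one group over another with a
two-sided p from a t reference at the contrast's residual degrees of freedom
(a normal reference is anticonservative at typical group sizes); BH adjustment
per contrast over the tested genes.

Calibration of the test (type-I error, planted-effect recovery) is the design
surface; exact numerical parity with any particular DE package is not.
Hypergeometric over-representation with expected overlap counts is included
for downstream gene-set summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable, ValidationError
from .profile import bh_adjust

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

#: contrast label -> (reference group, test group); lfc is log2(test / reference)
CONTRASTS = {
    "KO_vs_KOFMT": ("KO", "KO_FMT"),
    "WT_vs_WTFMT": ("WT", "WT_FMT"),
    "KOFMT_vs_WT": ("KO_FMT", "WT"),
    "WTFMT_vs_KO": ("WT_FMT", "KO"),
}


def size_factors(counts: CountTable) -> pd.Series:
    """Median-of-ratios normalization factors.

    For each gene expressed in every sample, compute count / geometric mean;
    a sample's factor is the median of those ratios.  When no gene is nonzero
    everywhere, fall back to per-gene positive counts only, with a warning.
    """
    mat = counts.data.to_numpy(dtype=float)
    all_pos = np.all(mat > 0, axis=1)
    if all_pos.any():
        sub = mat[all_pos]
        log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    else:
        logger.warning("no gene nonzero in all samples; positive-count fallback")
        with np.errstate(divide="ignore"):
            logs = np.where(mat > 0, np.log(mat), np.nan)
        log_geo = np.nanmean(logs, axis=1, keepdims=True)
        ratios = logs - log_geo
        factors = np.exp(np.nanmedian(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


@dataclass
class DispersionEstimates:
    table: pd.DataFrame  # gene-indexed: baseMean, raw_alpha, fitted_alpha, final_alpha


def estimate_dispersion(counts: CountTable, sf: pd.Series, meta: pd.DataFrame,
                        group_col: str = "group", prior_df: float = 8.0) -> DispersionEstimates:
    """Moment dispersion per gene, pooled over groups, shrunk to a trend.

    raw alpha solves Var(z) = m * mean(1/sf) + alpha * m^2 on normalized
    counts z pooled within groups; the trend is a robust log-log linear fit of
    raw alpha on baseMean; the final value is a residual-d.f.-weighted
    geometric combination of raw and trend, floored at 1e-8.
    """
    meta = meta.loc[list(counts.sample_ids)]
    groups = meta[group_col].unique()
    mat = counts.data.to_numpy(dtype=float)
    sfv = sf.loc[counts.sample_ids].to_numpy()
    z = mat / sfv[None, :]
    base_mean = z.mean(axis=1)
    n_groups_used = 0
    num = np.zeros(mat.shape[0])
    den = np.zeros(mat.shape[0])
    resid_df = 0
    for grp in groups:
        cols = np.where((meta[group_col] == grp).to_numpy())[0]
        if len(cols) < 2:
            continue
        n_groups_used += 1
        resid_df += len(cols) - 1
        zg = z[:, cols]
        m = zg.mean(axis=1)
        v = zg.var(axis=1, ddof=1)
        shot = m * np.mean(1.0 / sfv[cols])
        num += (v - shot) * (len(cols) - 1)
        den += m ** 2 * (len(cols) - 1)
    if n_groups_used == 0:
        raise ValidationError("dispersion needs >= 2 replicates in some group")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, np.nan)
    raw = np.where(np.isfinite(raw), raw, np.nan)
    raw_clipped = np.clip(raw, 0.0, None)

    ok = (base_mean > 0) & np.isfinite(raw) & (raw > 1e-6)
    if ok.sum() >= 10:
        import statsmodels.api as sm

        x = sm.add_constant(np.log(base_mean[ok]))
        fit = sm.RLM(np.log(raw[ok]), x, M=sm.robust.norms.HuberT()).fit()
        coef = fit.params
        with np.errstate(divide="ignore"):
            fitted = np.exp(coef[0] + coef[1] * np.log(np.maximum(base_mean, 1e-8)))
    else:
        med = np.nanmedian(raw_clipped[base_mean > 0]) if np.isfinite(raw).any() else 0.01
        fitted = np.full_like(base_mean, max(med, 1e-4))
    fitted = np.clip(fitted, 1e-8, 10.0)

    w_raw = max(resid_df - n_groups_used + 1, 1)
    log_raw = np.log(np.maximum(raw_clipped, 1e-8))
    log_final = (w_raw * log_raw + prior_df * np.log(fitted)) / (w_raw + prior_df)
    final = np.where(np.isnan(raw), fitted, np.exp(log_final))
    final = np.maximum(final, 1e-8)
    table = pd.DataFrame({
        "baseMean": base_mean, "raw_alpha": raw_clipped,
        "fitted_alpha": fitted, "final_alpha": final,
    }, index=counts.feature_ids)
    return DispersionEstimates(table=table)


def _fit_group_log_mean(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray,
                        max_iter: int = 50, tol: float = 1e-10):
    """Newton scoring for the per-group NB log-mean, vectorized over genes.

    Returns (beta, info): beta = log of the fitted group mean q (natural log),
    info = expected information at the optimum.  Genes with all-zero counts in
    the group get a small floor mean.
    """
    n_genes = y.shape[0]
    q0 = (y / sf[None, :]).mean(axis=1)
    floor = 1e-8
    beta = np.log(np.maximum(q0, floor))
    converged = np.zeros(n_genes, dtype=bool)
    for _ in range(max_iter):
        mu = np.exp(beta)[:, None] * sf[None, :]
        w = mu / (1.0 + alpha[:, None] * mu)
        score = ((y - mu) / (1.0 + alpha[:, None] * mu)).sum(axis=1)
        info = w.sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -3.0, 3.0)
        beta = beta + np.where(converged, 0.0, step)
        converged |= np.abs(step) < tol
        if converged.all():
            break
    mu = np.exp(beta)[:, None] * sf[None, :]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return beta, info, converged


def nb_wald_test(counts: CountTable, sf: pd.Series, dispersions: DispersionEstimates,
                 meta: pd.DataFrame, contrast: str | tuple[str, str],
                 group_col: str = "group") -> pd.DataFrame:
    """Per-gene NB Wald test of one group against another.

    ``contrast`` is a label from :data:`CONTRASTS` or a (reference, test)
    tuple; the reported log2FC is log2(mean_test / mean_reference).  Genes with
    all-zero counts across both groups are excluded before testing, and BH
    adjustment runs over the tested genes only.
    """
    if isinstance(contrast, str):
        if contrast not in CONTRASTS:
            raise ValidationError(f"unknown contrast {contrast!r}")
        ref, test = CONTRASTS[contrast]
        label = contrast
    else:
        ref, test = contrast
        label = f"{ref}_vs_{test}"
    meta = meta.loc[list(counts.sample_ids)]
    for grp in (ref, test):
        if not (meta[group_col] == grp).any():
            raise ValidationError(f"group {grp!r} absent from metadata")
    cols_ref = np.where((meta[group_col] == ref).to_numpy())[0]
    cols_test = np.where((meta[group_col] == test).to_numpy())[0]
    mat = counts.data.to_numpy(dtype=float)
    sfv = sf.loc[counts.sample_ids].to_numpy()
    used = mat[:, np.concatenate([cols_ref, cols_test])].sum(axis=1) > 0
    y = mat[used]
    alpha = dispersions.table["final_alpha"].to_numpy()[used]
    base_mean = (y / sfv[None, :]).mean(axis=1)

    b_ref, i_ref, c_ref = _fit_group_log_mean(y[:, cols_ref], sfv[cols_ref], alpha)
    b_test, i_test, c_test = _fit_group_log_mean(y[:, cols_test], sfv[cols_test], alpha)
    lfc = (b_test - b_ref) / LN2
    se = np.sqrt(1.0 / np.maximum(i_ref, 1e-12) + 1.0 / np.maximum(i_test, 1e-12)) / LN2
    z = lfc / se
    # t reference with the contrast's residual d.f.: the plug-in dispersion
    # makes a normal reference anticonservative at small n
    df_resid = max(len(cols_ref) + len(cols_test) - 2, 1)
    p = 2.0 * stats.t.sf(np.abs(z), df=df_resid)
    bad = ~(c_ref & c_test)
    if bad.any():
        logger.warning("%d gene(s) did not converge; p set to NA", int(bad.sum()))
        p = np.where(bad, np.nan, p)
    out = pd.DataFrame({
        "baseMean": base_mean, "log2FC": lfc, "se": se, "wald_z": z,
        "p": p, "padj": bh_adjust(p), "contrast_label": label,
    }, index=pd.Index(np.array(counts.feature_ids)[used], name="gene_id"))
    return out


def run_contrasts(counts: CountTable, meta: pd.DataFrame,
                  contrasts=tuple(CONTRASTS)) -> dict[str, pd.DataFrame]:
    """Convenience: size factors + dispersions + all requested contrasts."""
    sf = size_factors(counts)
    disp = estimate_dispersion(counts, sf, meta)
    return {c: nb_wald_test(counts, sf, disp, meta, c) for c in contrasts}


def ora_enrichment(de_genes, gene_sets: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of DE genes in each gene set.

    expected = de_size * set_size / universe (the product of gene ratio and
    background ratio scaled to the universe); p is the exact upper tail
    P(overlap >= observed); BH across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    de = set(de_genes) & universe
    rows = []
    for set_id, members in gene_sets.items():
        members = set(members) & universe
        overlap = len(members & de)
        expected = len(de) * len(members) / len(universe)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(de)))
        rows.append((set_id, overlap, len(members), len(de), len(universe), expected, p))
    out = pd.DataFrame(rows, columns=[
        "set_id", "overlap", "set_size", "de_size", "universe", "expected", "p_hyper",
    ]).set_index("set_id")
    out["padj"] = bh_adjust(out["p_hyper"])
    return out
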