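"""End-to-end orchestration: simulate -> profile -> source attribution -> DE ->
signature/network/clusters -> gene-taxon correlation, under one seed.

Stages communicate via files (TSV/JSON) in the output directory so each stage
is independently re-runnable; a machine-readable summary records parameters,
per-stage seeds, output checksums and headline counts.  A single master seed
is expanded per stage through a counter-based scheme.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as de_mod
from . import integration, profile, signature as sig_mod, sourcetrack, synthio
from .io import CountTable, write_count_table, write_metadata, write_taxonomy

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.8g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    out_dir: str = "fmtx_run"
    seed: int = 1
    simulation: synthio.SimulationConfig = field(default_factory=synthio.SimulationConfig)
    source: sourcetrack.SourceAttributionConfig = field(
        default_factory=sourcetrack.SourceAttributionConfig)
    signature: sig_mod.SignatureConfig = field(default_factory=sig_mod.SignatureConfig)
    n_permutations: int = 999
    css_quantile: float | str = "auto"


def _stage_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence([master, 1000 + k]).generate_state(1)[0] % (2 ** 31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic-cohort analysis; return the summary dict.

    All outputs and ``summary.json`` are written under ``cfg.out_dir``.
    Any stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "parameters": {
        "simulation": asdict(cfg.simulation),
        "source": asdict(cfg.source),
        "signature": asdict(cfg.signature),
        "n_permutations": cfg.n_permutations,
        "css_quantile": cfg.css_quantile,
    }, "counts": {}, "stages": {}}

    # --- stage 1: simulate ------------------------------------------------
    stage = "simulate"
    try:
        sim_cfg = synthio.SimulationConfig(**{**asdict(cfg.simulation), "seed": cfg.seed})
        data = synthio.simulate_dataset(sim_cfg)
        write_count_table(data.asv_counts, out / "asv_counts.tsv")
        write_taxonomy(data.taxonomy, out / "taxonomy.tsv")
        write_metadata(data.asv_meta, out / "metadata.tsv")
        write_count_table(data.gene_counts, out / "gene_counts.tsv")
        data.edges.to_csv(out / "edges.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        data.truth.to_json(out / "truth.json")
        summary["stages"][stage] = {"seed": cfg.seed}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 2: microbiome profile --------------------------------------
    stage = "profile"
    try:
        seed = _stage_seed(cfg.seed, 2)
        alpha = profile.alpha_diversity(data.asv_counts)
        _write(alpha, out / "alpha_diversity.tsv")
        genus = profile.collapse_genus(data.asv_counts, data.taxonomy)
        css = profile.css_normalize(genus, quantile=cfg.css_quantile)
        _write(css.normalized, out / "genus_css.tsv")
        dist = profile.bray_curtis(css.normalized)
        perm = profile.permanova(dist, data.asv_meta, ["genotype", "treatment"],
                                 n_perm=cfg.n_permutations, seed=seed)
        _write(perm, out / "permanova.tsv")
        rda = profile.rda_constrained(css.normalized, data.asv_meta,
                                      ["genotype", "treatment"],
                                      n_perm=cfg.n_permutations, seed=seed)
        css_asv = profile.css_normalize(data.asv_counts, quantile=cfg.css_quantile)
        diffabund = {}
        diffabund_asv = {}
        lefse_pass = {}
        clades = profile.expand_ranks(data.asv_counts, data.taxonomy)
        for genotype in ("WT", "KO"):
            da = profile.diff_abundance_paired(css.normalized, data.asv_meta,
                                               genotype=genotype)
            _write(da, out / f"diffabund_{genotype}.tsv")
            diffabund[genotype] = da
            diffabund_asv[genotype] = profile.diff_abundance_paired(
                css_asv.normalized, data.asv_meta, genotype=genotype)
            meta_g = data.asv_meta[data.asv_meta["genotype"] == genotype]
            lef = profile.lefse_lite(clades[list(meta_g.index)], meta_g, "treatment",
                                     seed=seed)
            _write(lef, out / f"lefse_{genotype}.tsv")
            lefse_pass[genotype] = int(lef["passes"].sum())
        summary["stages"][stage] = {"seed": seed, "css_quantile": css.quantile}
        summary["counts"]["permanova_R2"] = {
            f: round(float(v), 6) for f, v in perm["R2"].items()}
        summary["counts"]["rda_variance_fraction"] = {
            f: round(v, 6) for f, v in rda.constrained_variance_fractions.items()}
        summary["counts"]["rda_p"] = rda.p_perm
        summary["counts"]["lefse_passing_clades"] = lefse_pass
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 3: source attribution ---------------------------------------
    stage = "sourcetrack"
    try:
        seed = _stage_seed(cfg.seed, 3)
        src_cfg = sourcetrack.SourceAttributionConfig(
            **{**asdict(cfg.source), "seed": seed})
        meta = data.asv_meta
        sources = {
            genotype: data.asv_counts.subset_samples(
                meta.index[(meta["genotype"] == genotype) & (meta["treatment"] == "control")])
            for genotype in ("WT", "KO")
        }
        sinks = data.asv_counts.subset_samples(meta.index[meta["treatment"] == "FMT"])
        estimates = sourcetrack.gibbs_source_proportions(sources, sinks, src_cfg)
        est = sourcetrack.estimates_to_frame(estimates)
        _write(est, out / "source_proportions.tsv")
        donor = {}
        for genotype, donor_label in (("WT", "KO"), ("KO", "WT")):
            fmt_ids = [s for s in est.index
                       if meta.loc[s, "genotype"] == genotype]
            vals = est.loc[fmt_ids, donor_label]
            donor[f"{donor_label}_to_{genotype}FMT"] = {
                "mean": round(float(vals.mean()), 6), "sd": round(float(vals.std(ddof=1)), 6)}
        summary["stages"][stage] = {"seed": seed}
        summary["counts"]["donor_proportion"] = donor
        summary["counts"]["per_sink_donor_proportion"] = {
            s: round(float(est.loc[s, "KO" if meta.loc[s, "genotype"] == "WT" else "WT"]), 6)
            for s in est.index}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 4: differential expression ----------------------------------
    stage = "de"
    try:
        contrasts = de_mod.run_contrasts(data.gene_counts, data.gene_meta)
        for label, table in contrasts.items():
            _write(table, out / f"de_{label}.tsv")
        summary["stages"][stage] = {}
        summary["counts"]["n_de_genes"] = {
            label: int((tbl["padj"] < cfg.signature.padj_threshold).sum())
            for label, tbl in contrasts.items()}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 5: core signature -------------------------------------------
    stage = "signature"
    try:
        sig = sig_mod.extract_opposite_signature(
            contrasts["KO_vs_KOFMT"], contrasts["WT_vs_WTFMT"], cfg.signature)
        sig = sig_mod.classify_restoration(
            sig, contrasts["KOFMT_vs_WT"], contrasts["WTFMT_vs_KO"],
            cfg.signature.padj_threshold)
        _write(sig, out / "signature.tsv")
        net = sig_mod.build_network(sig.index, data.edges, cfg.signature)
        nx_edges = pd.DataFrame(
            [(u, v, d["weight"]) for u, v, d in net.edges(data=True)],
            columns=["gene_a", "gene_b", "score"],
        ).sort_values(["gene_a", "gene_b"])
        nx_edges.to_csv(out / "network.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        clusters = sig_mod.clusterone_clusters(net, cfg.signature)
        _write(sig_mod.clusters_to_frame(clusters), out / "clusters.tsv")
        summary["stages"][stage] = {}
        summary["counts"].update({
            "n_signature_genes": int(len(sig)),
            "n_restored_genes": int((sig["restored"] == True).sum()),  # noqa: E712
            "network_nodes": int(net.number_of_nodes()),
            "network_edges": int(net.number_of_edges()),
            "n_clusters": len(clusters),
            "n_significant_clusters": sum(1 for c in clusters if c.significant),
        })
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 6: gene-taxon integration -------------------------------------
    stage = "integration"
    try:
        sf = de_mod.size_factors(data.gene_counts)
        norm_expr = np.log2(data.gene_counts.data / sf + 1.0)
        taxa_log = np.log2(css_asv.normalized + 1.0)
        all_edges = []
        for genotype, label in (("WT", "WT_vs_WTFMT"), ("KO", "KO_vs_KOFMT")):
            tbl = contrasts[label]
            responsive = tbl.index[tbl["padj"] < cfg.signature.padj_threshold]
            if len(responsive) == 0:
                continue
            cand = integration.correlate_gene_taxon(
                norm_expr.loc[responsive], taxa_log, data.gene_meta, genotype)
            kept = integration.sign_consistency_filter(
                cand, gene_lfc=tbl["log2FC"],
                taxon_lfc=diffabund_asv[genotype]["median_lfc_proxy"],
                lfc_threshold=cfg.signature.lfc_threshold,
                opposite_genes=sig.index,
            )
            all_edges.append(kept)
        corr = pd.concat(all_edges, ignore_index=True) if all_edges else pd.DataFrame(
            columns=["gene_id", "taxon_id", "genotype", "r", "p", "padj",
                     "candidate", "gene_lfc", "taxon_lfc", "sign_consistent", "kept"])
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        mixed = integration.assemble_mixed_network(corr, net, signature_genes=sig.index)
        summary["stages"][stage] = {}
        summary["counts"].update({
            "n_candidate_correlations": int(corr["candidate"].sum()) if len(corr) else 0,
            "n_kept_correlations": int(corr["kept"].sum()) if len(corr) else 0,
            "taxon_linked_signature_fraction": round(mixed.taxon_linked_fraction, 6),
        })
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- summary -------------------------------------------------------------
    checksums = {}
    for path in sorted(out.glob("*.tsv")) + [out / "truth.json"]:
        checksums[path.name] = _sha256(path)
    summary["checksums"] = checksums
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
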