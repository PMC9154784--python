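"""Synthetic reciprocal-FMT study generator with a machine-readable ground truth.

Emulates a two-genotype (WT, KO) mouse cohort in which each genotype receives a
fecal microbiota transplant from the other, giving four groups: WT, KO, WT_FMT
(WT mice carrying KO-derived microbiota) and KO_FMT (the reverse).  The
generator plants, and records in a :class:`TruthManifest`:

* genotype-specific taxa (a fraction of taxa enriched in one genotype),
* donor engraftment — each FMT group's expected composition is a mixture of the
  donor and recipient base compositions at a direction-specific transfer rate
  (0.65 for KO->WT recipients, 0.27 for WT->KO, mirroring the asymmetry the
  assay is designed to detect),
* opposite-direction genes — up upon FMT in one genotype, down in the other,
  fully reversed toward the donor genotype's baseline (so they read as
  "restored" in cross-genotype comparisons),
* same-sign confounder genes responding to the transplant procedure itself,
* gene-taxon correlations: for selected opposite genes, the expression mean of
  each FMT sample tracks that sample's measured (CSS-normalized, log2) level of
  a named donor-enriched taxon, with a recorded sign; a smaller set is planted
  sign-INconsistently (the correlation is real but contradicts the fold-change
  signs) so the downstream consistency filter has true negatives to remove,
* cohesive interaction-network modules among opposite genes.

ASV counts are Dirichlet-multinomial per sample; gene counts are negative
binomial with log-normal library-size factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountTable, RANKS, group_label

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "SyntheticDataset",
    "simulate_asv_table",
    "simulate_gene_counts",
    "simulate_interaction_edges",
    "simulate_dataset",
    "expected_group_compositions",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""

    def __init__(self, fieldname: str, message: str):
        self.field = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic reciprocal-FMT cohort."""

    n_per_group: int = 10
    n_taxa: int = 120
    n_genes: int = 2000
    n_opposite_genes: int = 60
    n_same_sign_genes: int = 30
    n_planted_correlations: int = 30
    n_spurious_correlations: int = 10
    nb_dispersion: float = 0.2
    effect_lfc: float = 1.5
    taxon_shift_fraction: float = 0.3
    #: (rate into WT recipients from KO donors, rate into KO recipients from WT)
    fmt_transfer_rate: tuple[float, float] = (0.65, 0.27)
    genotype_fold_log2: float = 3.0
    dirichlet_concentration: float = 50.0
    asv_depth_log_mean: float = float(np.log(2e4))
    asv_depth_log_sigma: float = 0.3
    gene_libsize_log_sigma: float = 0.25
    gene_mean_log_mu: float = float(np.log(300.0))
    gene_mean_log_sigma: float = 1.0
    #: natural-log sd of the planted gene-taxon link across FMT samples
    corr_link_gamma: float = 0.6
    corr_gene_dispersion: float = 0.005
    corr_gene_min_expression: float = 500.0
    module_count: int = 3
    module_size: int = 8
    module_edge_prob: float = 0.9
    background_edge_prob: float = 0.02
    seed: int = 1

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group", "must be >= 2")
        for name in ("n_taxa", "n_genes"):
            if getattr(self, name) < 1:
                raise ConfigError(name, "must be positive")
        if not 0 <= self.n_opposite_genes <= self.n_genes:
            raise ConfigError("n_opposite_genes", "must lie in [0, n_genes]")
        if self.n_opposite_genes + self.n_same_sign_genes > self.n_genes:
            raise ConfigError("n_same_sign_genes", "planted genes exceed n_genes")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion", "must be >= 0")
        if not 0 <= self.taxon_shift_fraction < 1:
            raise ConfigError("taxon_shift_fraction", "must lie in [0, 1)")
        for i, r in enumerate(self.fmt_transfer_rate):
            if not 0 < r <= 1:
                raise ConfigError("fmt_transfer_rate", f"rate {i} not in (0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration", "must be > 0")
        if self.n_planted_correlations + self.n_spurious_correlations > self.n_opposite_genes:
            raise ConfigError(
                "n_planted_correlations",
                "planted + spurious correlations exceed the opposite-gene pool",
            )


@dataclass
class TruthManifest:
    """Ground truth of a simulated cohort, for recovery scoring."""

    opposite_gene_ids: list = field(default_factory=list)
    same_sign_gene_ids: list = field(default_factory=list)
    #: gene -> (true lfc in KO_vs_KOFMT, true lfc in WT_vs_WTFMT), log2 scale
    gene_true_lfc_per_contrast: dict = field(default_factory=dict)
    #: dicts with keys gene, taxon, sign (+1/-1), genotype, spurious (bool)
    planted_edges: list = field(default_factory=list)
    #: FMT sample -> {source genotype: expected mixing proportion}
    source_mixtures: dict = field(default_factory=dict)
    #: taxon -> "WT" | "KO" | "none"
    genotype_taxa: dict = field(default_factory=dict)
    #: gene id lists of planted cohesive interaction modules
    planted_modules: list = field(default_factory=list)
    #: latent (pre-multinomial) taxon proportions, {sample: {taxon: p}}
    latent_proportions: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def validate(self, gene_ids=None, taxon_ids=None) -> None:
        for edge in self.planted_edges:
            if gene_ids is not None and edge["gene"] not in gene_ids:
                raise ValueError(f"planted edge references unknown gene {edge['gene']}")
            if taxon_ids is not None and edge["taxon"] not in taxon_ids:
                raise ValueError(f"planted edge references unknown taxon {edge['taxon']}")
        for sample, mix in self.source_mixtures.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"source mixture of {sample} does not sum to 1")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sample_ids(cfg: SimulationConfig) -> dict[str, list[str]]:
    out = {}
    for genotype in ("WT", "KO"):
        for treatment in ("control", "FMT"):
            grp = group_label(genotype, treatment)
            out[grp] = [f"{grp}_{i + 1:02d}" for i in range(cfg.n_per_group)]
    return out


def _base_compositions(cfg: SimulationConfig, rng: np.random.Generator):
    """Shared log-normal backbone with genotype-specific enrichment folds."""
    taxa = [f"ASV{i + 1:04d}" for i in range(cfg.n_taxa)]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_taxa)
    n_shift = int(round(cfg.taxon_shift_fraction * cfg.n_taxa))
    idx = rng.permutation(cfg.n_taxa)[:n_shift]
    wt_taxa, ko_taxa = idx[: n_shift // 2], idx[n_shift // 2:]
    fold = 2.0 ** cfg.genotype_fold_log2
    w_wt, w_ko = base.copy(), base.copy()
    w_wt[wt_taxa] *= fold
    w_ko[wt_taxa] /= fold
    w_ko[ko_taxa] *= fold
    w_wt[ko_taxa] /= fold
    w_wt /= w_wt.sum()
    w_ko /= w_ko.sum()
    labels = {t: "none" for t in taxa}
    for i in wt_taxa:
        labels[taxa[i]] = "WT"
    for i in ko_taxa:
        labels[taxa[i]] = "KO"
    return taxa, w_wt, w_ko, labels


def expected_group_compositions(cfg: SimulationConfig) -> pd.DataFrame:
    """Analytic expected taxon proportions per group (before any sampling).

    FMT mixing acts here, on expected proportions: the engraftment
    interpretation of the transfer rate.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    taxa, w_wt, w_ko, _ = _base_compositions(cfg, rng)
    r_wt, r_ko = cfg.fmt_transfer_rate
    comp = {
        "WT": w_wt,
        "KO": w_ko,
        "WT_FMT": r_wt * w_ko + (1 - r_wt) * w_wt,
        "KO_FMT": r_ko * w_wt + (1 - r_ko) * w_ko,
    }
    return pd.DataFrame(comp, index=taxa)


def _make_taxonomy(taxa: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Plausible 7-rank lineages with shared genera; ~10% unassigned at genus."""
    n_phyla, n_families, n_genera = 5, 15, 40
    phyla = [f"Phylum{i + 1}" for i in range(n_phyla)]
    rows = []
    fam_of_genus = rng.integers(0, n_families, size=n_genera)
    phy_of_family = rng.integers(0, n_phyla, size=n_families)
    for t in taxa:
        g = int(rng.integers(0, n_genera))
        f = int(fam_of_genus[g])
        p = int(phy_of_family[f])
        genus = f"Genus{g + 1}" if rng.random() > 0.1 else ""
        rows.append(
            {
                "Kingdom": "Bacteria",
                "Phylum": phyla[p],
                "Class": f"Class{p + 1}",
                "Order": f"Order{f % 8 + 1}",
                "Family": f"Family{f + 1}",
                "Genus": genus,
                "Species": "",
            }
        )
    return pd.DataFrame(rows, index=pd.Index(taxa, name="ASV"), columns=list(RANKS))


def simulate_asv_table(cfg: SimulationConfig):
    """Simulate the 16S side: counts, taxonomy, metadata and truth manifest.

    Returns ``(CountTable, taxonomy DataFrame, metadata DataFrame,
    TruthManifest)``.  Per-sample counts are Dirichlet-multinomial around the
    group's expected composition; library sizes are log-normal.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    taxa, w_wt, w_ko, labels = _base_compositions(cfg, rng)
    taxonomy = _make_taxonomy(taxa, rng)
    ids = _sample_ids(cfg)
    r_wt, r_ko = cfg.fmt_transfer_rate
    expected = {
        "WT": w_wt,
        "KO": w_ko,
        "WT_FMT": r_wt * w_ko + (1 - r_wt) * w_wt,
        "KO_FMT": r_ko * w_wt + (1 - r_ko) * w_ko,
    }
    manifest = TruthManifest(genotype_taxa=labels, params={"config": asdict(cfg)})
    counts = {}
    meta_rows = []
    for grp, samples in ids.items():
        genotype = "WT" if grp.startswith("WT") else "KO"
        treatment = "FMT" if grp.endswith("FMT") else "control"
        for j, s in enumerate(samples):
            p = rng.dirichlet(cfg.dirichlet_concentration * expected[grp])
            # proportions sum to 1 by construction before the multinomial draw
            depth = int(rng.lognormal(cfg.asv_depth_log_mean, cfg.asv_depth_log_sigma))
            counts[s] = rng.multinomial(depth, p)
            manifest.latent_proportions[s] = {t: float(x) for t, x in zip(taxa, p)}
            meta_rows.append(
                {"sample": s, "genotype": genotype, "treatment": treatment,
                 "pair_id": f"{genotype}{j + 1:02d}"}
            )
            if treatment == "FMT":
                donor = "KO" if genotype == "WT" else "WT"
                rate = r_wt if genotype == "WT" else r_ko
                manifest.source_mixtures[s] = {donor: rate, genotype: 1 - rate}
    table = CountTable(pd.DataFrame(counts, index=taxa))
    meta = pd.DataFrame(meta_rows).set_index("sample")
    meta["group"] = [group_label(g, t) for g, t in zip(meta["genotype"], meta["treatment"])]
    manifest.validate(taxon_ids=set(taxa))
    return table, taxonomy, meta, manifest


def _plan_planted_edges(cfg, gene_signs, opposite_ids, labels, abundance_rank=None):
    """Allocate gene-taxon links: consistent edges per genotype plus spurious.

    All planted taxa are donor-enriched in the target genotype (they rise
    strongly after FMT), so the taxon fold-change sign is unambiguous; the
    gene is then chosen so the product of fold-change signs matches (or, for
    spurious edges, contradicts) the correlation sign.  Links are planted on
    the most abundant enriched taxa first (``abundance_rank``: taxon -> mean
    latent proportion) — a correlation planted on a taxon near the sequencing
    detection floor would measure multinomial noise, not the method.
    """
    wt_enriched = [t for t, l in labels.items() if l == "WT"]
    ko_enriched = [t for t, l in labels.items() if l == "KO"]
    if not wt_enriched or not ko_enriched:
        return []
    if abundance_rank is not None:
        wt_enriched = sorted(wt_enriched, key=lambda t: -abundance_rank.get(t, 0.0))
        ko_enriched = sorted(ko_enriched, key=lambda t: -abundance_rank.get(t, 0.0))
        n_keep = max(4, (cfg.n_planted_correlations + cfg.n_spurious_correlations) // 5)
        wt_enriched = wt_enriched[:n_keep]
        ko_enriched = ko_enriched[:n_keep]
    pos_genes = iter([g for g in opposite_ids if gene_signs[g] > 0])
    neg_genes = iter([g for g in opposite_ids if gene_signs[g] < 0])
    edges = []

    def take(it):
        try:
            return next(it)
        except StopIteration:
            return None

    def taxon_for(genotype, k):
        pool = ko_enriched if genotype == "WT" else wt_enriched
        return pool[k % len(pool)]

    n_cons, n_spur = cfg.n_planted_correlations, cfg.n_spurious_correlations
    for k in range(n_cons):
        genotype = "WT" if k % 2 == 0 else "KO"
        r_sign = 1 if (k // 2) % 2 == 0 else -1
        # gene lfc in this genotype's contrast: WT contrast = -s*e, KO = +s*e
        if genotype == "WT":
            want_s = -r_sign  # lfc_B = -s*e must share r's sign
        else:
            want_s = r_sign
        gene = take(pos_genes if want_s > 0 else neg_genes)
        if gene is None:
            break
        edges.append({"gene": gene, "taxon": taxon_for(genotype, k), "sign": r_sign,
                      "genotype": genotype, "spurious": False})
    for k in range(n_spur):
        genotype = "WT" if k % 2 == 0 else "KO"
        # r > 0 but the gene's fold-change opposes the taxon's (which is up)
        want_s = 1 if genotype == "WT" else -1  # gene lfc negative in-genotype
        gene = take(pos_genes if want_s > 0 else neg_genes)
        if gene is None:
            break
        edges.append({"gene": gene, "taxon": taxon_for(genotype, k + n_cons),
                      "sign": 1, "genotype": genotype, "spurious": True})
    return edges


def simulate_gene_counts(cfg: SimulationConfig, taxon_proportions: pd.DataFrame | None = None,
                         genotype_taxa: dict | None = None,
                         taxon_measured: pd.DataFrame | None = None):
    """Simulate the transcriptome side: NB gene counts, metadata, truth manifest.

    ``taxon_proportions`` (samples x taxa latent proportions from
    :func:`simulate_asv_table`) ranks the taxa eligible for planted
    correlations; ``taxon_measured`` (samples x taxa, log2 CSS-normalized
    abundances of the same cohort) is the signal planted gene means track.  If
    omitted, an ASV simulation with the same config is run internally so the
    operation stands alone.
    """
    cfg.validate()
    if taxon_proportions is None:
        counts, _, _, asv_manifest = simulate_asv_table(cfg)
        taxon_proportions = pd.DataFrame(asv_manifest.latent_proportions).T
        genotype_taxa = asv_manifest.genotype_taxa
        from .profile import css_normalize

        taxon_measured = css_normalize(counts, log2=True).normalized.T
    if taxon_measured is None:
        taxon_measured = np.log(taxon_proportions + 1e-9)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    ids = _sample_ids(cfg)
    samples = [s for grp in ("WT", "KO", "WT_FMT", "KO_FMT") for s in ids[grp]]
    meta_rows = []
    for grp in ("WT", "KO", "WT_FMT", "KO_FMT"):
        genotype = "WT" if grp.startswith("WT") else "KO"
        treatment = "FMT" if grp.endswith("FMT") else "control"
        for j, s in enumerate(ids[grp]):
            meta_rows.append({"sample": s, "genotype": genotype, "treatment": treatment,
                              "pair_id": f"{genotype}{j + 1:02d}"})
    meta = pd.DataFrame(meta_rows).set_index("sample")
    meta["group"] = [group_label(g, t) for g, t in zip(meta["genotype"], meta["treatment"])]

    base = rng.lognormal(cfg.gene_mean_log_mu, cfg.gene_mean_log_sigma, size=cfg.n_genes)
    perm = rng.permutation(cfg.n_genes)
    opp_idx = perm[: cfg.n_opposite_genes]
    same_idx = perm[cfg.n_opposite_genes: cfg.n_opposite_genes + cfg.n_same_sign_genes]
    opposite_ids = [genes[i] for i in opp_idx]
    same_ids = [genes[i] for i in same_idx]

    e = cfg.effect_lfc
    mu = pd.DataFrame(
        np.tile(base[:, None], (1, 4)), index=genes, columns=["WT", "KO", "WT_FMT", "KO_FMT"]
    )
    gene_signs = {}
    manifest = TruthManifest(
        opposite_gene_ids=list(opposite_ids), same_sign_gene_ids=list(same_ids),
        params={"config": asdict(cfg)},
    )
    for k, gi in enumerate(opp_idx):
        s = 1 if k % 2 == 0 else -1
        gene_signs[genes[gi]] = s
        m = base[gi]
        # full reversal: each recipient group moves to the donor genotype's level
        mu.iloc[gi] = [m * 2 ** (s * e / 2), m * 2 ** (-s * e / 2),
                       m * 2 ** (-s * e / 2), m * 2 ** (s * e / 2)]
        manifest.gene_true_lfc_per_contrast[genes[gi]] = (s * e, -s * e)
    for k, gi in enumerate(same_idx):
        s = 1 if k % 2 == 0 else -1
        mu.loc[genes[gi], ["WT_FMT", "KO_FMT"]] = base[gi] * 2 ** (s * e)
        manifest.gene_true_lfc_per_contrast[genes[gi]] = (s * e, s * e)
    for g in genes:
        manifest.gene_true_lfc_per_contrast.setdefault(g, (0.0, 0.0))

    labels = genotype_taxa or {}
    abundance_rank = taxon_proportions.mean(axis=0).to_dict()
    edges = _plan_planted_edges(cfg, gene_signs, opposite_ids, labels, abundance_rank)
    manifest.planted_edges = edges

    size_factors = rng.lognormal(0.0, cfg.gene_libsize_log_sigma, size=len(samples))
    group_of = meta["group"].to_dict()
    mu_samples = np.empty((cfg.n_genes, len(samples)))
    for j, s in enumerate(samples):
        mu_samples[:, j] = mu[group_of[s]].to_numpy() * size_factors[j]

    # planted correlation links: modulate FMT-sample means by the latent taxon
    # abundance, mean-normalized within the group so the planted lfc is kept
    alpha = np.full(cfg.n_genes, cfg.nb_dispersion)
    gene_pos = {g: i for i, g in enumerate(genes)}
    col_pos = {s: j for j, s in enumerate(samples)}
    for edge in edges:
        grp = f"{edge['genotype']}_FMT"
        cols = [col_pos[s] for s in ids[grp]]
        v = taxon_measured.loc[ids[grp], edge["taxon"]].to_numpy(dtype=float)
        sd = v.std()
        zv = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        factor = np.exp(cfg.corr_link_gamma * edge["sign"] * zv)
        factor /= factor.mean()
        gi = gene_pos[edge["gene"]]
        # linked genes are kept highly expressed so the correlation measures
        # the planted link rather than counting shot noise; the uniform scale
        # preserves every planted fold-change
        mu_samples[gi, :] *= max(1.0, cfg.corr_gene_min_expression / base[gi])
        mu_samples[gi, cols] *= factor
        alpha[gi] = cfg.corr_gene_dispersion

    if cfg.nb_dispersion == 0 and cfg.corr_gene_dispersion == 0:
        counts = rng.poisson(mu_samples)
    else:
        a = np.maximum(alpha, 1e-8)[:, None]
        counts = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * mu_samples))
    table = CountTable(pd.DataFrame(counts, index=genes, columns=samples))
    manifest.params["size_factors"] = {s: float(f) for s, f in zip(samples, size_factors)}
    manifest.validate(gene_ids=set(genes), taxon_ids=set(taxon_proportions.columns) or None)
    return table, meta, manifest


def simulate_interaction_edges(cfg: SimulationConfig, gene_ids: list[str],
                               manifest: TruthManifest | None = None) -> pd.DataFrame:
    """Scored gene-gene edges with planted cohesive modules among opposite genes.

    Within-module pairs get high scores with probability ``module_edge_prob``;
    background pairs are sparse with uniform scores.  Returns a gene_a /
    gene_b / score DataFrame; module memberships are appended to ``manifest``.
    """
    cfg.validate()
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    module_pool = manifest.opposite_gene_ids if manifest is not None else list(gene_ids)
    module_pool = [g for g in module_pool if g in set(gene_ids)]
    modules = []
    k = cfg.module_size
    for m in range(cfg.module_count):
        members = module_pool[m * k: (m + 1) * k]
        if len(members) >= 3:
            modules.append(members)
    rows = []
    seen = set()
    for members in modules:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < cfg.module_edge_prob:
                    rows.append((members[i], members[j], rng.uniform(0.55, 0.99)))
                    seen.add(frozenset((members[i], members[j])))
    genes = list(gene_ids)
    n = len(genes)
    if cfg.background_edge_prob > 0 and n > 1:
        n_bg = rng.binomial(n * (n - 1) // 2, cfg.background_edge_prob)
        while n_bg > 0:
            i, j = rng.integers(0, n, size=2)
            if i == j or frozenset((genes[i], genes[j])) in seen:
                continue
            rows.append((genes[i], genes[j], rng.uniform(0.0, 1.0)))
            seen.add(frozenset((genes[i], genes[j])))
            n_bg -= 1
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    if manifest is not None:
        manifest.planted_modules = [list(m) for m in modules]
    return edges


@dataclass
class SyntheticDataset:
    asv_counts: CountTable
    taxonomy: pd.DataFrame
    asv_meta: pd.DataFrame
    gene_counts: CountTable
    gene_meta: pd.DataFrame
    edges: pd.DataFrame
    truth: TruthManifest


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Full coordinated cohort: shared mice between the 16S and RNA tables."""
    from .profile import css_normalize

    asv_counts, taxonomy, asv_meta, asv_truth = simulate_asv_table(cfg)
    latent = pd.DataFrame(asv_truth.latent_proportions).T
    measured = css_normalize(asv_counts, log2=True).normalized.T
    gene_counts, gene_meta, truth = simulate_gene_counts(
        cfg, taxon_proportions=latent, genotype_taxa=asv_truth.genotype_taxa,
        taxon_measured=measured,
    )
    truth.source_mixtures = asv_truth.source_mixtures
    truth.genotype_taxa = asv_truth.genotype_taxa
    truth.latent_proportions = asv_truth.latent_proportions
    edge_pool = truth.opposite_gene_ids + truth.same_sign_gene_ids
    extra = [g for g in gene_counts.feature_ids if g not in set(edge_pool)][:120]
    edges = simulate_interaction_edges(cfg, edge_pool + extra, manifest=truth)
    return SyntheticDataset(asv_counts, taxonomy, asv_meta, gene_counts, gene_meta, edges, truth)
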