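"""Microbial source attribution by collapsed Gibbs sampling.

Estimates, per recipient (sink) sample, the posterior fraction of its
community attributable to each donor (source) environment plus an "unknown"
source.  Reads of a rarefied sink are assigned to environments; known
environments keep a fixed taxon profile (their pooled training counts with a
scaled Dirichlet prior alpha1), while the unknown environment's profile is
learned from its currently assigned reads under a symmetric prior beta.

Proportions are averaged over post-burn-in draws within a restart and then
over independent restarts; the standard deviation across restart means is
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gibbs import gibbs_one_chain
from .io import CountTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SourceAttributionConfig:
    alpha1: float = 0.001
    alpha2: float = 0.001
    beta: float = 10.0
    rarefaction_depth: int = 1000
    n_burnin: int = 100
    n_draws: int = 25
    restarts: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha1", "alpha2", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")


@dataclass
class SourceEstimate:
    sink_sample_id: str
    proportions: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)


def rarefy(counts: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads
    (multivariate hypergeometric); samples below depth are dropped with a
    warning."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    keep, cols = [], {}
    for s in counts.sample_ids:
        x = counts.data[s].to_numpy()
        total = int(x.sum())
        if total < depth:
            logger.warning("dropping sample %s: %d reads < depth %d", s, total, depth)
            continue
        if total == depth:
            cols[s] = x.copy()
        else:
            cols[s] = rng.multivariate_hypergeometric(x, depth)
        keep.append(s)
    if not keep:
        raise ValidationError(f"all samples fall below rarefaction depth {depth}")
    return CountTable(pd.DataFrame(cols, index=counts.feature_ids))


def gibbs_source_proportions(sources: dict[str, CountTable], sinks: CountTable,
                             cfg: SourceAttributionConfig) -> list[SourceEstimate]:
    """Estimate mixing proportions of each sink over the source environments
    plus "unknown".

    ``sources`` maps environment label -> CountTable of that environment's
    samples (pooled into one training profile); taxa indices must match the
    sink table.  Sinks are rarefied to ``cfg.rarefaction_depth`` first.
    """
    cfg.validate()
    if not sources:
        raise ValidationError("at least one source environment required")
    if not sinks.sample_ids:
        raise ValidationError("empty sink table")
    labels = sorted(sources)
    taxa = sinks.feature_ids
    train = np.zeros((len(labels), len(taxa)))
    for v, lab in enumerate(labels):
        tbl = sources[lab]
        if list(tbl.feature_ids) != list(taxa):
            tbl_data = tbl.data.reindex(taxa, fill_value=0)
        else:
            tbl_data = tbl.data
        train[v] = tbl_data.sum(axis=1).to_numpy()
    m_v = train.sum(axis=1)
    if np.any(m_v == 0):
        raise ValidationError(f"source environment {labels[int(np.argmax(m_v == 0))]!r} is empty")
    # scaled-prior likelihood: (m_xv + alpha1 * m_v) / (m_v * (1 + alpha1));
    # the per-environment denominator is constant across environments and
    # cancels in the normalization over environments
    known_lik = (train + cfg.alpha1 * m_v[:, None]) / (m_v * (1 + cfg.alpha1))[:, None]

    rare = rarefy(sinks, cfg.rarefaction_depth, seed=cfg.seed)
    estimates = []
    env_names = labels + ["unknown"]
    for si, sink in enumerate(rare.sample_ids):
        x = rare.data[sink].to_numpy()
        reads = np.repeat(np.arange(len(taxa), dtype=np.int32), x).astype(np.int32)
        restart_means = np.zeros((cfg.restarts, len(env_names)))
        for r in range(cfg.restarts):
            chain_seed = (cfg.seed * 100003 + si * 1009 + r * 7 + 1) % (2 ** 31 - 1)
            draws = gibbs_one_chain(
                known_lik, reads, cfg.alpha2, cfg.beta,
                cfg.n_burnin, cfg.n_draws, chain_seed,
            )
            restart_means[r] = draws.mean(axis=0)
        mean = restart_means.mean(axis=0)
        sd = restart_means.std(axis=0, ddof=1) if cfg.restarts > 1 else np.zeros_like(mean)
        estimates.append(SourceEstimate(
            sink_sample_id=sink,
            proportions={k: float(v) for k, v in zip(env_names, mean)},
            sd={k: float(v) for k, v in zip(env_names, sd)},
        ))
    return estimates


def estimates_to_frame(estimates: list[SourceEstimate]) -> pd.DataFrame:
    rows = {}
    for est in estimates:
        row = dict(est.proportions)
        row.update({f"sd_{k}": v for k, v in est.sd.items()})
        rows[est.sink_sample_id] = row
    out = pd.DataFrame(rows).T
    out.index.name = "sink"
    return out
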