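"""Compiled inner loop of the collapsed Gibbs sampler for source attribution.

One sink is processed at a time.  Known source environments contribute a fixed
per-taxon likelihood (their training counts with a scaled Dirichlet prior);
the extra "unknown" environment's taxon distribution is learned from the reads
currently assigned to it, under a symmetric prior ``beta``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_one_chain(known_lik, reads, alpha2, beta, n_burnin, n_draws, seed):
    """Run one chain; return (n_draws, V+1) per-draw environment proportions.

    known_lik : (V, T) array, p(taxon | known source v) with prior smoothing.
    reads     : (depth,) int32 taxon index of each sink read.
    """
    np.random.seed(seed)
    n_sources, n_taxa = known_lik.shape
    n_env = n_sources + 1
    depth = reads.shape[0]
    z = np.empty(depth, dtype=np.int64)
    env_counts = np.zeros(n_env, dtype=np.int64)
    unknown_taxon = np.zeros(n_taxa, dtype=np.int64)
    # initialize over the known sources only: the unknown environment starts
    # empty (it would otherwise begin as a copy of the sink profile and trap
    # the chain); it fills up during sweeps from reads the sources cannot
    # explain
    for i in range(depth):
        v = np.random.randint(0, n_sources)
        z[i] = v
        env_counts[v] += 1

    draws = np.zeros((n_draws, n_env))
    probs = np.empty(n_env)
    prior = depth * alpha2
    for sweep in range(n_burnin + n_draws):
        for i in range(depth):
            x = reads[i]
            v_old = z[i]
            env_counts[v_old] -= 1
            if v_old == n_sources:
                unknown_taxon[x] -= 1
            total = 0.0
            for v in range(n_sources):
                p = known_lik[v, x] * (env_counts[v] + prior)
                probs[v] = p
                total += p
            p_unk = ((unknown_taxon[x] + beta)
                     / (env_counts[n_sources] + beta * n_taxa)
                     * (env_counts[n_sources] + prior))
            probs[n_sources] = p_unk
            total += p_unk
            u = np.random.random() * total
            acc = 0.0
            v_new = n_env - 1
            for v in range(n_env):
                acc += probs[v]
                if u <= acc:
                    v_new = v
                    break
            z[i] = v_new
            env_counts[v_new] += 1
            if v_new == n_sources:
                unknown_taxon[x] += 1
        if sweep >= n_burnin:
            for v in range(n_env):
                draws[sweep - n_burnin, v] = env_counts[v] / depth
    return draws
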