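"""Chinese-restaurant-process clustering of promoter rank profiles.

Promoter time courses are rank-transformed within each subject (highest of
the T time points -> rank T, lowest -> 1, ties averaged) and clustered with a
Dirichlet-process mixture Gibbs sampler: each mixture component is an
independent Gaussian per dimension with a conjugate Normal-Inverse-Gamma
prior, so cluster marginal likelihoods and predictive densities are closed
form and promoters can be reassigned by collapsed Gibbs sampling.  Several
independent sampler processes are run and the partition with the highest log
marginal posterior (CRP prior x marginal likelihood) over all sampled states
is returned.  Inverted profiles are NOT treated as similar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

N_PROCESSES = 100
N_CYCLES = 100
ALPHA = 1.0


def rank_profiles(expression: pd.DataFrame, design: pd.DataFrame,
                  time_order: list[str] | None = None) -> pd.DataFrame:
    """Within-subject rank transform of promoter time courses.

    ``expression`` is promoters x samples; ``design`` maps samples to
    (subject, time).  For each subject the T time-point values of a promoter
    are replaced by ranks 1..T (average ranks on ties).  Subjects missing a
    time point are dropped (logged via the returned column set).  Columns of
    the result are ``{subject}:{time}`` in subject-major order.
    """
    times = time_order or list(pd.unique(design["time"]))
    blocks = []
    for subject, sub in design.groupby("subject", sort=True):
        if not all(t in set(sub["time"]) for t in times):
            continue
        cols = [sub[sub["time"] == t].index[0] for t in times]
        vals = expression[cols]
        ranks = vals.rank(axis=1, method="average")
        ranks.columns = [f"{subject}:{t}" for t in times]
        blocks.append(ranks)
    if not blocks:
        raise ValueError("no subject has a complete time course")
    return pd.concat(blocks, axis=1)


@dataclass
class ClusterPartition:
    labels: pd.Series              # promoter_id -> cluster label (0..K-1)
    log_posterior: float
    process_scores: list[float]    # best score of each sampler process
    chosen_process: int

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


class _NIG:
    """Per-dimension Normal-Inverse-Gamma marginal likelihood bookkeeping."""

    def __init__(self, mu0, kappa0, a0, b0):
        self.mu0, self.k0, self.a0, self.b0 = mu0, kappa0, a0, b0

    def log_marginal(self, n, s, ss):
        """Marginal likelihood of a cluster: n points, per-dim sums s, sumsq ss."""
        if n == 0:
            return 0.0
        k0, a0, b0, mu0 = self.k0, self.a0, self.b0, self.mu0
        kn = k0 + n
        an = a0 + n / 2.0
        ybar = s / n
        bn = b0 + 0.5 * (ss - n * ybar ** 2) + k0 * n * (ybar - mu0) ** 2 / (2 * kn)
        bn = np.maximum(bn, 1e-300)
        per_dim = (
            gammaln(an) - gammaln(a0) + a0 * np.log(b0) - an * np.log(bn)
            + 0.5 * (np.log(k0) - np.log(kn)) - (n / 2.0) * np.log(2 * np.pi)
        )
        return float(np.sum(per_dim))


def _crp_log_prior(sizes, alpha, n):
    sizes = np.asarray(sizes, dtype=float)
    return (
        len(sizes) * np.log(alpha)
        + gammaln(sizes).sum()
        + gammaln(alpha)
        - gammaln(alpha + n)
    )


def crc_cluster(ranks, n_processes: int = N_PROCESSES, n_cycles: int = N_CYCLES,
                alpha: float = ALPHA, seed=None, mu0: float | None = None,
                kappa0: float = 1.0, a0: float = 2.0, b0: float = 1.0
                ) -> ClusterPartition:
    """Cluster rank profiles with a DP-mixture collapsed Gibbs sampler.

    Parameters
    ----------
    ranks
        Promoters x dimensions (subject-by-time rank values); DataFrame or
        array.
    n_processes, n_cycles
        Independent sampler restarts and Gibbs sweeps per restart.
    alpha
        CRP concentration.
    mu0, kappa0, a0, b0
        Normal-Inverse-Gamma prior; ``mu0`` defaults to the midpoint of the
        observed rank scale ((1+T)/2 for full rank data).

    The returned partition is the MAP over every state visited by every
    process.
    """
    if isinstance(ranks, pd.DataFrame):
        index = ranks.index
        X = ranks.to_numpy(dtype=float)
    else:
        X = np.asarray(ranks, dtype=float)
        index = pd.RangeIndex(len(X))
    n, D = X.shape if X.ndim == 2 else (len(X), 1)
    X = X.reshape(n, D)
    if n == 0:
        return ClusterPartition(pd.Series(dtype=int), -np.inf, [], -1)
    if mu0 is None:
        mu0 = 0.5 * (X.min() + X.max())
    prior = _NIG(mu0, kappa0, a0, b0)
    X2 = X ** 2
    rng = np.random.default_rng(seed)

    best_labels, best_score, best_proc = None, -np.inf, -1
    process_scores = []

    for proc in range(n_processes):
        prng = np.random.default_rng(rng.integers(2 ** 31))
        # sequential CRP initialization using the predictive density
        labels = np.full(n, -1, dtype=int)
        sums, sumsqs, counts = [], [], []
        order = prng.permutation(n)
        for i in order:
            logp = []
            for c in range(len(counts)):
                lp = (np.log(counts[c])
                      + prior.log_marginal(counts[c] + 1, sums[c] + X[i],
                                           sumsqs[c] + X2[i])
                      - prior.log_marginal(counts[c], sums[c], sumsqs[c]))
                logp.append(lp)
            logp.append(np.log(alpha) + prior.log_marginal(1, X[i], X2[i]))
            logp = np.asarray(logp)
            pr = np.exp(logp - logp.max())
            c = prng.choice(len(pr), p=pr / pr.sum())
            if c == len(counts):
                counts.append(0)
                sums.append(np.zeros(D))
                sumsqs.append(np.zeros(D))
            labels[i] = c
            counts[c] += 1
            sums[c] = sums[c] + X[i]
            sumsqs[c] = sumsqs[c] + X2[i]

        def score_state():
            lp = _crp_log_prior([c for c in counts if c > 0], alpha, n)
            for c in range(len(counts)):
                if counts[c] > 0:
                    lp += prior.log_marginal(counts[c], sums[c], sumsqs[c])
            return lp

        proc_best = score_state()
        proc_best_labels = labels.copy()

        for _ in range(n_cycles):
            for i in prng.permutation(n):
                c_old = labels[i]
                counts[c_old] -= 1
                sums[c_old] = sums[c_old] - X[i]
                sumsqs[c_old] = sumsqs[c_old] - X2[i]
                live = [c for c in range(len(counts)) if counts[c] > 0]
                logp = np.empty(len(live) + 1)
                for j, c in enumerate(live):
                    logp[j] = (np.log(counts[c])
                               + prior.log_marginal(counts[c] + 1, sums[c] + X[i],
                                                    sumsqs[c] + X2[i])
                               - prior.log_marginal(counts[c], sums[c], sumsqs[c]))
                logp[-1] = np.log(alpha) + prior.log_marginal(1, X[i], X2[i])
                pr = np.exp(logp - logp.max())
                pick = prng.choice(len(pr), p=pr / pr.sum())
                if pick == len(live):
                    c_new = next(
                        (c for c in range(len(counts)) if counts[c] == 0), None
                    )
                    if c_new is None:
                        c_new = len(counts)
                        counts.append(0)
                        sums.append(np.zeros(D))
                        sumsqs.append(np.zeros(D))
                else:
                    c_new = live[pick]
                labels[i] = c_new
                counts[c_new] += 1
                sums[c_new] = sums[c_new] + X[i]
                sumsqs[c_new] = sumsqs[c_new] + X2[i]
            sc = score_state()
            if sc > proc_best:
                proc_best, proc_best_labels = sc, labels.copy()

        process_scores.append(proc_best)
        if proc_best > best_score:
            best_score, best_labels, best_proc = proc_best, proc_best_labels, proc

    # relabel clusters densely by decreasing size
    uniq, inv = np.unique(best_labels, return_inverse=True)
    sizes = np.bincount(inv)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    final = pd.Series(remap[inv], index=index, name="cluster")
    return ClusterPartition(final, float(best_score), process_scores, best_proc)
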