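"""Paired differential expression and Dirichlet-multinomial differential TSS usage.

Differential expression is assessed per post-stress time point against the
baseline on a paired design: counts are normalized by median-of-ratios size
factors, each subject contributes a log2 ratio (pseudo-count 1), and a
one-sample t-test asks whether the mean log ratio differs from zero.  Flags
use the |fold change| > 1.25 and BH-adjusted p < 0.01 thresholds.

Differential TSS usage (DTU) asks whether the proportional split of a gene's
expression over its K TSS clusters differs between baseline and a time point.
Per-sample cluster-count vectors are modelled as Dirichlet-multinomial
DM(pi, gamma) with proportion vector pi and precision gamma (larger gamma =
closer to multinomial).  The test is a likelihood-ratio test of one shared pi
(null) against one pi per condition (alternative), gamma shared and profiled
out by maximum likelihood, with a chi-square(K-1) reference distribution and
BH correction across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import digamma, gammaln
from scipy.stats import chi2, t as t_dist
from statsmodels.stats.multitest import multipletests

DEFAULT_FC_MIN = 1.25
DEFAULT_DE_ALPHA = 0.01
DEFAULT_DTU_ALPHA = 0.05
LOG_GAMMA_BOUNDS = (np.log(0.01), np.log(1e4))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (one per sample/column)."""
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    allpos = np.isfinite(logmat).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no unit has positive counts in every sample; supply a "
            "pseudo-reference or filter samples"
        )
    log_geomean = logmat[allpos].mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logmat[allpos] - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def test_de(counts: pd.DataFrame, design: pd.DataFrame, baseline: str = "pre",
            fc_min: float = DEFAULT_FC_MIN, alpha: float = DEFAULT_DE_ALPHA,
            exclude: tuple = ("2min",)) -> pd.DataFrame:
    """Paired differential expression per time point vs baseline.

    Parameters
    ----------
    counts
        Units (genes or promoters) x samples, nonnegative integers.
    design
        Indexed by sample name with columns ``subject`` and ``time``.
    exclude
        Time points generated but never tested (e.g. the early 2-min sample).

    Returns one row per (unit, time point): log2fc, p, padj, deg, tested.
    Units with all-zero counts in a comparison are reported untested.
    """
    sf = size_factors(counts)
    norm = counts / sf
    results = []
    time_points = [
        tp for tp in pd.unique(design["time"]) if tp != baseline and tp not in exclude
    ]
    tiny = np.finfo(float).tiny
    for tp in time_points:
        base = design[design["time"] == baseline]
        post = design[design["time"] == tp]
        subjects = [s for s in base["subject"] if s in set(post["subject"])]
        if len(subjects) < 3:
            raise ValueError(f"fewer than 3 complete subject pairs for {tp}")
        b_cols = [base[base["subject"] == s].index[0] for s in subjects]
        t_cols = [post[post["subject"] == s].index[0] for s in subjects]
        nb = norm[b_cols].to_numpy()
        nt = norm[t_cols].to_numpy()
        tested = ~((nb.sum(axis=1) == 0) & (nt.sum(axis=1) == 0))
        d = np.log2(nt + 1) - np.log2(nb + 1)
        mean_d = d.mean(axis=1)
        sd = d.std(axis=1, ddof=1)
        n = d.shape[1]
        p = np.full(len(counts), np.nan)
        degenerate = (sd == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = mean_d / (sd / np.sqrt(n))
        nondeg = tested & ~degenerate
        p[nondeg] = 2 * t_dist.sf(np.abs(tstat[nondeg]), df=n - 1)
        p[tested & degenerate & (mean_d == 0)] = 1.0
        p[tested & degenerate & (mean_d != 0)] = tiny
        padj = bh_adjust(np.where(tested, p, np.nan))
        fc = np.power(2.0, mean_d)
        abs_fc = np.maximum(fc, 1 / fc)
        deg = tested & (abs_fc > fc_min) & (padj < alpha)
        results.append(pd.DataFrame(dict(
            unit_id=counts.index, time=tp, log2fc=np.where(tested, mean_d, np.nan),
            fold_change=np.where(tested, fc, np.nan), p=p, padj=padj,
            deg=deg, tested=tested,
            degenerate=tested & degenerate & (mean_d != 0),
        )))
    return pd.concat(results, ignore_index=True)


# ---------------------------------------------------------------------------
# Dirichlet-multinomial likelihood and DTU test

def dm_loglik(x, pi, gamma) -> float:
    """Log pmf of the Dirichlet-multinomial DM(x; pi, gamma).

    ``log n!/(prod x_k!) + lgamma(gamma) - lgamma(n+gamma)
    + sum_k [lgamma(x_k + gamma*pi_k) - lgamma(gamma*pi_k)]`` with n = sum x.
    A zero pi_k with x_k > 0 gives -inf (zero probability).
    """
    x = np.asarray(x, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must sum to 1")
    if np.any((pi == 0) & (x > 0)):
        return -np.inf
    n = x.sum()
    coeff = gammaln(n + 1) - gammaln(x + 1).sum()
    a = gamma * pi
    nz = pi > 0
    return float(
        coeff + gammaln(gamma) - gammaln(n + gamma)
        + (gammaln(x[nz] + a[nz]) - gammaln(a[nz])).sum()
    )


def _dm_ll(X: np.ndarray, pi: np.ndarray, gamma: float) -> float:
    """Joint DM log-likelihood over rows of X, dropping the x-only coefficient."""
    n = X.sum(axis=1)
    a = gamma * pi
    return float(
        (gammaln(gamma) - gammaln(n + gamma)).sum()
        + (gammaln(X + a) - gammaln(a)).sum()
    )


def fit_dm_pi(X: np.ndarray, gamma: float, tol: float = 1e-8,
              max_iter: int = 500) -> np.ndarray:
    """MLE of the DM proportion vector at fixed precision gamma.

    Multiplicative fixed-point ascent ``pi_k <- pi_k * g_k / sum(pi g)`` with
    ``g_k = sum_i [psi(x_ik + gamma pi_k) - psi(gamma pi_k)]``; iteration
    stops when the log-likelihood improves by less than ``tol``.
    """
    X = np.asarray(X, dtype=float)
    pi = X.sum(axis=0) + 0.5
    pi = pi / pi.sum()
    ll = _dm_ll(X, pi, gamma)
    for _ in range(max_iter):
        a = gamma * pi
        g = (digamma(X + a) - digamma(a)).sum(axis=0)
        new = pi * g
        s = new.sum()
        if s <= 0 or not np.isfinite(s):
            break
        new = np.clip(new / s, 1e-12, None)
        new /= new.sum()
        new_ll = _dm_ll(X, new, gamma)
        if new_ll < ll - 1e-10:  # fixed point overshoot; keep previous
            break
        pi, improved = new, new_ll - ll
        ll = new_ll
        if improved < tol:
            break
    return pi


def _profile_ll(groups: list[np.ndarray]):
    """Maximized DM log-likelihood with gamma shared and profiled out.

    Each group gets its own proportion vector; returns
    ``(loglik, gamma_hat, [pi_hat per group])``.
    """

    def negll(log_gamma):
        gamma = np.exp(log_gamma)
        return -sum(_dm_ll(X, fit_dm_pi(X, gamma), gamma) for X in groups)

    res = minimize_scalar(
        negll, bounds=LOG_GAMMA_BOUNDS, method="bounded",
        options={"xatol": 1e-4},
    )
    gamma = float(np.exp(res.x))
    pis = [fit_dm_pi(X, gamma) for X in groups]
    return -float(res.fun), gamma, pis


def dtu_lrt(X_base: np.ndarray, X_alt: np.ndarray):
    """DM likelihood-ratio test of shared vs per-condition proportions.

    Returns a dict with lrt, df, p, gamma (alternative fit), pi_base, pi_alt.
    """
    X_base = np.asarray(X_base, dtype=float)
    X_alt = np.asarray(X_alt, dtype=float)
    K = X_base.shape[1]
    ll0, _, (pi0,) = _profile_ll([np.vstack([X_base, X_alt])])
    ll1, gamma1, (pib, pit) = _profile_ll([X_base, X_alt])
    lrt = max(0.0, 2 * (ll1 - ll0))
    df = K - 1
    return dict(
        lrt=lrt, df=df, p=float(chi2.sf(lrt, df)), gamma=gamma1,
        pi_null=pi0, pi_base=pib, pi_alt=pit,
    )


def test_dtu(cluster_counts: pd.DataFrame, annotation: pd.DataFrame,
             design: pd.DataFrame, baseline: str = "pre",
             alpha: float = DEFAULT_DTU_ALPHA, exclude: tuple = ("2min",),
             min_samples: int = 3) -> pd.DataFrame:
    """Differential TSS usage per gene per time point.

    Parameters
    ----------
    cluster_counts
        Robust-cluster counts (clusters x samples), indexed by cluster_id.
    annotation
        cluster_id -> gene_id mapping (clusters without a gene are ignored).
    design
        Indexed by sample with ``subject`` and ``time`` columns.

    Genes with a single cluster, or with an all-zero condition, are reported
    untested.  BH correction is applied across genes within each time point.
    """
    gene_of = annotation.set_index("cluster_id")["gene_id"]
    time_points = [
        tp for tp in pd.unique(design["time"]) if tp != baseline and tp not in exclude
    ]
    base_cols = design[design["time"] == baseline].index.tolist()
    rows = []
    for tp in time_points:
        t_cols = design[design["time"] == tp].index.tolist()
        if len(base_cols) < min_samples or len(t_cols) < min_samples:
            raise ValueError(f"fewer than {min_samples} samples per condition for {tp}")
        for gene, ids in gene_of.dropna().groupby(gene_of.dropna()).groups.items():
            ids = [c for c in ids if c in cluster_counts.index]
            K = len(ids)
            rec = dict(gene_id=gene, time=tp, K=K, lrt=np.nan, p=np.nan,
                       gamma=np.nan, tested=False)
            if K >= 2:
                Xb = cluster_counts.loc[ids, base_cols].to_numpy().T
                Xt = cluster_counts.loc[ids, t_cols].to_numpy().T
                if Xb.sum() > 0 and Xt.sum() > 0:
                    fit = dtu_lrt(Xb, Xt)
                    rec.update(lrt=fit["lrt"], p=fit["p"], gamma=fit["gamma"],
                               tested=True)
            rows.append(rec)
    out = pd.DataFrame(rows)
    out["padj"] = np.nan
    for tp in time_points:
        m = out["time"] == tp
        out.loc[m, "padj"] = bh_adjust(out.loc[m, "p"])
    out["dtu"] = out["tested"] & (out["padj"] < alpha)
    return out
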