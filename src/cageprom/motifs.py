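"""PWM scanning with per-matrix threshold calibration and TFBS enrichment.

Each position count matrix becomes a log2-odds weight matrix; a per-matrix
score cutoff is calibrated on the background promoter set so that the
both-strand hit frequency does not exceed 1 site per 2000 bp; promoter
sequences are scanned on both strands (overlapping same-strand hits reduced
greedily to the best-scoring non-overlapping set); and enrichment of each
matrix in differentially regulated (foreground) promoters relative to non-DE
background promoters is scored two ways: a site-rate ratio with a one-sided
binomial test, and a promoter-hit odds ratio with Fisher's exact test.  The
adjusted fold enrichment FE_adj is the lower bound of the two-sided 99%
confidence interval of the log rate/odds ratio (Haldane 1/2 corrections for
sparse tables); a matrix is enriched when either statistic shows
FE_adj > 1.5 at FDR < 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import binomtest, fisher_exact

from .differential import bh_adjust
from .io import PWMRecord

TARGET_SITE_FREQ = 1.0 / 2000.0
FE_MIN = 1.5
FDR_MAX = 0.05
Z99 = 2.5758

_ENC = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3; anything else (N) -> 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pwm_logodds(pwm: PWMRecord, background=None, pseudocount: float = 1.0) -> np.ndarray:
    """Position-specific log2-odds weights.

    ``w(b, j) = log2(((count(b,j) + pc*bg_b) / (N_j + pc)) / bg_b)`` with
    N_j the column total.  Returns an array of shape (length, 4).
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background frequencies must be positive and sum to 1")
    counts = pwm.counts
    totals = counts.sum(axis=1, keepdims=True)
    if pseudocount == 0 and np.any(totals == 0):
        raise ValueError("zero column total requires a positive pseudocount")
    return np.log2((counts + pseudocount * bg) / (totals + pseudocount) / bg)


def max_score(weights: np.ndarray) -> float:
    """Maximum attainable log-odds score of the matrix."""
    return float(weights.max(axis=1).sum())


def _window_scores(enc: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scores of every window of one encoded strand; N windows -> -inf."""
    L = weights.shape[0]
    if len(enc) < L:
        return np.empty(0)
    wext = np.vstack([weights.T, np.full((1, L), -np.inf)])  # row 4 = N
    win = sliding_window_view(enc, L)
    return wext[win, np.arange(L)].sum(axis=1)


def _revcomp_enc(enc: np.ndarray) -> np.ndarray:
    rc = enc[::-1].copy()
    acgt = rc < 4
    rc[acgt] = 3 - rc[acgt]
    return rc


def both_strand_scores(seq_or_enc, weights: np.ndarray):
    """(forward scores, reverse scores) for all windows of a sequence."""
    enc = (
        encode_sequence(seq_or_enc) if isinstance(seq_or_enc, str) else seq_or_enc
    )
    return _window_scores(enc, weights), _window_scores(_revcomp_enc(enc), weights)


def calibrate_threshold(weights: np.ndarray, background_seqs: dict[str, str],
                        target_freq: float = TARGET_SITE_FREQ,
                        min_total_bp: int = 100_000) -> float:
    """Smallest score cutoff with background both-strand hit rate <= target.

    The rate is raw hit windows (both strands) divided by the total bp of the
    background set.  If even the matrix's maximum attainable score is
    exceeded too often, the maximum score is returned with a warning.
    """
    if not background_seqs:
        raise ValueError("background sequence set is empty")
    total_bp = sum(len(s) for s in background_seqs.values())
    if total_bp < min_total_bp:
        raise ValueError(
            f"background too small for calibration ({total_bp} bp < {min_total_bp})"
        )
    scores = []
    for s in background_seqs.values():
        fwd, rev = both_strand_scores(s, weights)
        scores.append(fwd[np.isfinite(fwd)])
        scores.append(rev[np.isfinite(rev)])
    scores = np.concatenate(scores) if scores else np.empty(0)
    allowed = int(np.floor(target_freq * total_bp))
    mx = max_score(weights)
    if len(scores) == 0:
        return mx
    desc = np.sort(scores)[::-1]
    if allowed >= len(desc):
        return float(desc[-1])
    # unique score values in descending order with cumulative counts
    uniq, first_idx = np.unique(-desc, return_index=True)
    uniq = -uniq  # descending
    cum = np.array([np.searchsorted(-desc, -u, side="right") for u in uniq])
    ok = cum <= allowed
    if not ok.any():
        n_at_max = int(np.searchsorted(-desc, -mx, side="right"))
        if n_at_max > allowed:
            warnings.warn(
                "even the maximum matrix score exceeds the target site "
                "frequency; using the maximum score as cutoff"
            )
        return mx
    return float(uniq[ok][-1])


def scan_sequence(seq_or_enc, weights: np.ndarray, cutoff: float) -> list[tuple]:
    """Hits (pos, strand, score) at ``score >= cutoff``, both strands.

    Overlapping same-strand hits are reduced greedily to the best-scoring
    non-overlapping set (ties broken leftmost).
    """
    enc = (
        encode_sequence(seq_or_enc) if isinstance(seq_or_enc, str) else seq_or_enc
    )
    L = weights.shape[0]
    n = len(enc)
    fwd, rev = both_strand_scores(enc, weights)
    hits = []
    for strand, scores in (("+", fwd), ("-", rev)):
        idx = np.flatnonzero(scores >= cutoff)
        if len(idx) == 0:
            continue
        pos = idx if strand == "+" else n - L - idx
        cand = sorted(zip(-scores[idx], pos), key=lambda t: (t[0], t[1]))
        occupied = np.zeros(n, dtype=bool)
        for negscore, p in cand:
            if not occupied[p:p + L].any():
                occupied[p:p + L] = True
                hits.append((int(p), strand, float(-negscore)))
    return sorted(hits)


def scan_sequences(pwm: PWMRecord, cutoff: float, sequences: dict[str, str],
                   weights: np.ndarray | None = None) -> pd.DataFrame:
    """Scan a set of named sequences; returns a site table."""
    w = pwm_logodds(pwm) if weights is None else weights
    rows = []
    for name, seq in sequences.items():
        for pos, strand, score in scan_sequence(seq, w, cutoff):
            rows.append(dict(promoter_id=name, matrix_id=pwm.matrix_id,
                             pos=pos, strand=strand, score=score))
    return pd.DataFrame(rows, columns=["promoter_id", "matrix_id", "pos",
                                       "strand", "score"])


def _site_stats(sites: pd.DataFrame, seqs: dict[str, str]):
    n_sites = len(sites)
    n_hit_seqs = sites["promoter_id"].nunique() if n_sites else 0
    total_bp = sum(len(s) for s in seqs.values())
    return n_sites, n_hit_seqs, total_bp, len(seqs)


def enrichment_stats(sites_fg: int, bp_fg: int, seq_hits_fg: int, n_fg: int,
                     sites_bg: int, bp_bg: int, seq_hits_bg: int, n_bg: int,
                     z99: float = Z99) -> dict:
    """Enrichment statistics from foreground/background site and hit counts.

    FE_site is the site-rate ratio with a one-sided binomial p-value;
    FE_seq the promoter-hit odds ratio with Fisher's exact p-value; each
    FE_adj is the lower bound of the two-sided 99% CI of the log ratio
    (Haldane 1/2 corrections when a ratio is 0 or infinite).
    """
    sf, sb, bpf, bpb = sites_fg, sites_bg, bp_fg, bp_bg
    hf, hb, nf, nb = seq_hits_fg, seq_hits_bg, n_fg, n_bg
    rate_f, rate_b = sf / bpf, sb / bpb
    fe_site = np.inf if sb == 0 and sf > 0 else (
        0.0 if sf == 0 else rate_f / rate_b
    )
    fe_for_ci = fe_site if np.isfinite(fe_site) and fe_site > 0 else (
        ((sf + 0.5) / bpf) / ((sb + 0.5) / bpb)
    )
    se_site = np.sqrt(1 / (sf + 0.5) + 1 / (sb + 0.5))
    fe_adj_site = float(np.exp(np.log(fe_for_ci) - z99 * se_site))
    p_site = binomtest(
        sf, n=sf + sb, p=bpf / (bpf + bpb), alternative="greater"
    ).pvalue if sf + sb > 0 else 1.0

    a, b = hf, nf - hf                    # fg hit / miss
    c, d = hb, nb - hb                    # bg hit / miss
    fe_seq = (a * d) / (b * c) if b * c > 0 else (
        np.inf if a * d > 0 else np.nan
    )
    or_h = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    se_seq = np.sqrt(sum(1 / (x + 0.5) for x in (a, b, c, d)))
    fe_adj_seq = float(np.exp(np.log(or_h) - z99 * se_seq))
    p_seq = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
    return dict(
        sites_fg=sf, sites_bg=sb, bp_fg=bpf, bp_bg=bpb,
        seq_hits_fg=hf, seq_hits_bg=hb, n_fg=nf, n_bg=nb,
        fe_site=fe_site, fe_adj_site=fe_adj_site, p_site=p_site,
        fe_seq=fe_seq, fe_adj_seq=fe_adj_seq, p_seq=p_seq,
    )


def enrich(foreground: dict[str, str], background: dict[str, str],
           pwms: list[PWMRecord], fe_min: float = FE_MIN,
           fdr_max: float = FDR_MAX, z99: float = Z99,
           target_freq: float = TARGET_SITE_FREQ,
           min_background_bp: int = 100_000):
    """TFBS enrichment of foreground vs background promoter sequences.

    Per matrix: the cutoff is calibrated on the background set, both sets are
    scanned, and two enrichment statistics are computed — the site-rate ratio
    FE_site with a one-sided binomial test, and the promoter-hit odds ratio
    FE_seq with Fisher's exact test.  FE_adj is the 99%-CI lower bound of
    each ratio.  BH correction runs across matrices separately per statistic.

    Returns ``(per_matrix, per_tf)`` tables; per_tf keeps each factor's most
    enriched matrix (highest FE_adj).
    """
    if not foreground or not background:
        raise ValueError("foreground and background sets must be non-empty")
    rows = []
    for pwm in pwms:
        w = pwm_logodds(pwm)
        cutoff = calibrate_threshold(w, background, target_freq,
                                     min_total_bp=min_background_bp)
        fg_sites = scan_sequences(pwm, cutoff, foreground, weights=w)
        bg_sites = scan_sequences(pwm, cutoff, background, weights=w)
        sf, hf, bpf, nf = _site_stats(fg_sites, foreground)
        sb, hb, bpb, nb = _site_stats(bg_sites, background)
        stats = enrichment_stats(sf, bpf, hf, nf, sb, bpb, hb, nb, z99=z99)
        rows.append(dict(matrix_id=pwm.matrix_id, tf_name=pwm.tf_name,
                         cutoff=cutoff, **stats))
    res = pd.DataFrame(rows)
    res["fdr_site"] = bh_adjust(res["p_site"])
    res["fdr_seq"] = bh_adjust(res["p_seq"])
    res["enriched"] = (
        ((res["fe_adj_site"] > fe_min) & (res["fdr_site"] < fdr_max))
        | ((res["fe_adj_seq"] > fe_min) & (res["fdr_seq"] < fdr_max))
    )
    res["fe_adj_best"] = res[["fe_adj_site", "fe_adj_seq"]].max(axis=1)
    per_tf = (
        res.sort_values("fe_adj_best", ascending=False)
        .groupby("tf_name", sort=False)
        .head(1)
        .reset_index(drop=True)
    )
    return res, per_tf
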