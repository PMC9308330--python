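"""Aggregate stranded CAGE 5'-tag positions into TSS clusters and quantify them.

CAGE 5' tags mark transcription start positions at single-base resolution.
Nearby tag positions on the same strand are chained into TSS clusters by
single-linkage (consecutive positions at most ``max_gap`` bp apart join one
cluster), clusters are quantified as raw counts and tags-per-million (TPM),
the robust filter is applied, and per-cluster shape descriptors (count mass
center, interquantile width, sharp/broad class) are computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MAX_GAP = 20
SHARP_MAX_WIDTH = 10


def shape_metrics(positions, counts, q_low=0.25, q_high=0.75,
                  sharp_max_width=SHARP_MAX_WIDTH):
    """Shape descriptors of a tag-count distribution over positions.

    Returns ``(mass_center, iq_width, shape_class)`` where mass_center is the
    count-weighted mean position, iq_width the distance in bp between the
    discrete q_low and q_high quantile positions (inclusive), and shape_class
    ``"sharp"`` iff iq_width <= sharp_max_width else ``"broad"``.
    """
    positions = np.asarray(positions)
    counts = np.asarray(counts, dtype=float)
    order = np.argsort(positions)
    positions, counts = positions[order], counts[order]
    total = counts.sum()
    if total <= 0:
        raise ValueError("cluster has zero total tag count")
    mass_center = float((positions * counts).sum() / total)
    cum = np.cumsum(counts)
    pos_lo = positions[np.searchsorted(cum, q_low * total)]
    pos_hi = positions[np.searchsorted(cum, q_high * total)]
    iq_width = int(pos_hi - pos_lo + 1)
    shape_class = "sharp" if iq_width <= sharp_max_width else "broad"
    return mass_center, iq_width, shape_class


def cluster_tags(tag_table: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP):
    """Single-linkage clustering of CAGE tag positions per (chrom, strand).

    Parameters
    ----------
    tag_table
        Columns ``chrom``, ``pos``, ``strand`` plus one integer count column
        per sample.  Rows with the same position are summed.
    max_gap
        Consecutive tag positions at most this many bp apart join one cluster.

    Returns
    -------
    (clusters, counts)
        ``clusters``: DataFrame with cluster_id, chrom, start, end, strand,
        mass_center, iq_width, shape_class, total_count.
        ``counts``: DataFrame of per-sample tag counts indexed by cluster_id.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    sample_cols = [c for c in tag_table.columns if c not in ("chrom", "pos", "strand")]
    rows, count_rows = [], []
    if len(tag_table):
        grouped = (
            tag_table.groupby(["chrom", "strand", "pos"], sort=True)[sample_cols]
            .sum()
            .reset_index()
        )
        for (chrom, strand), sub in grouped.groupby(["chrom", "strand"], sort=True):
            pos = sub["pos"].to_numpy()
            cnt = sub[sample_cols].to_numpy(dtype=np.int64)
            breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
            for seg_pos, seg_cnt in zip(
                np.split(pos, breaks), np.split(cnt, breaks)
            ):
                totals = seg_cnt.sum(axis=1)
                mc, iqw, shape = shape_metrics(seg_pos, totals)
                rows.append(
                    dict(
                        chrom=chrom,
                        start=int(seg_pos[0]),
                        end=int(seg_pos[-1]) + 1,
                        strand=strand,
                        mass_center=mc,
                        iq_width=iqw,
                        shape_class=shape,
                        total_count=int(totals.sum()),
                    )
                )
                count_rows.append(seg_cnt.sum(axis=0))
    clusters = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "strand",
            "mass_center", "iq_width", "shape_class", "total_count",
        ],
    )
    clusters.insert(0, "cluster_id", [f"ctss_{i:05d}" for i in range(len(clusters))])
    counts = pd.DataFrame(
        count_rows, columns=sample_cols, index=clusters["cluster_id"], dtype=np.int64
    )
    counts.index.name = "cluster_id"
    return clusters, counts


def quantify(counts: pd.DataFrame, library_sizes) -> pd.DataFrame:
    """Tags-per-million: ``TPM_s = count_s / library_size_s * 1e6``."""
    library_sizes = pd.Series(library_sizes)
    missing = [s for s in counts.columns if s not in library_sizes.index]
    if missing:
        raise ValueError(f"missing library sizes for samples: {missing}")
    ls = library_sizes[counts.columns]
    if (ls <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts / ls * 1e6


def filter_robust(counts: pd.DataFrame, tpm: pd.DataFrame,
                  tpm_min: float = 1.0, count_min: int = 11) -> pd.Series:
    """Robust flag: some single sample has TPM >= tpm_min AND count >= count_min."""
    both = (tpm.to_numpy() >= tpm_min) & (counts.to_numpy() >= count_min)
    return pd.Series(both.any(axis=1), index=counts.index, name="robust")
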