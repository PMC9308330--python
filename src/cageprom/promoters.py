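"""Individual promoter regions from open chromatin, and TFBS density profiles.

A consensus open-chromatin track is built by merging replicate peak sets
within each assay (ATAC-seq, DNase-seq), intersecting the two assay tracks,
and joining resulting intervals separated by < 71 bp (less than half a
nucleosome's wrapped DNA).  A TSS cluster within 200 bp of a consensus
interval defines an individual (Open) promoter — clusters sharing an
interval share the promoter, which makes bidirectional promoters (member
clusters on both strands) a natural outcome.  Remaining clusters are chained
at <= 200 bp into pseudo-promoters: Closed200 if open chromatin lies within
2000 bp of the group anchor (chromatin "removed" from the promoter itself),
Closed2000 if none does.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GenomicInterval

log = logging.getLogger(__name__)

JOIN_GAP = 71
MAX_DIST = 200
CLOSED_BAND = 2000
PROMOTER_TYPES = ("Open", "Closed200", "Closed2000")


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per chromosome (overlapping or touching merge)."""
    out = []
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_intervals(a: list[GenomicInterval],
                        b: list[GenomicInterval]) -> list[GenomicInterval]:
    """Intersection of two merged interval sets."""
    out = []
    by_chrom_b: dict[str, list] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for iv in a:
        for s, e in by_chrom_b.get(iv.chrom, []):
            lo, hi = max(iv.start, s), min(iv.end, e)
            if lo < hi:
                out.append(GenomicInterval(iv.chrom, lo, hi))
    return sorted(out, key=lambda x: (x.chrom, x.start))


def join_close(intervals: list[GenomicInterval], join_gap: int = JOIN_GAP):
    """Join consecutive intervals whose gap is strictly below ``join_gap``."""
    out = []
    by_chrom: dict[str, list] = {}
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start)):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom in sorted(by_chrom):
        spans = by_chrom[chrom]
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s - cur_e < join_gap:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def consensus_open_chromatin(atac_replicates: list[list[GenomicInterval]],
                             dnase_replicates: list[list[GenomicInterval]],
                             join_gap: int = JOIN_GAP) -> list[GenomicInterval]:
    """Consensus open chromatin: per-assay union, assay intersection, joining.

    Replicate peak sets within each assay are merged (union); the two assay
    tracks are intersected; intervals separated by < ``join_gap`` bp are then
    joined (gap of exactly ``join_gap`` stays split).
    """
    tracks = []
    for name, reps in (("ATAC", atac_replicates), ("DNase", dnase_replicates)):
        flat = [iv for rep in reps for iv in rep]
        if not flat:
            log.warning("%s assay contributed no peaks; consensus is empty", name)
            return []
        tracks.append(merge_intervals(flat))
    return join_close(intersect_intervals(*tracks), join_gap)


def _gap(s1, e1, s2, e2) -> int:
    return max(0, max(s1, s2) - min(e1, e2))


def assign_promoters(open_intervals: list[GenomicInterval],
                     clusters: pd.DataFrame, tpm: pd.DataFrame,
                     baseline_samples: list[str], max_dist: int = MAX_DIST,
                     closed_band: int = CLOSED_BAND):
    """Group robust TSS clusters into promoters and pseudo-promoters.

    A cluster whose interval lies within ``max_dist`` bp of a consensus
    open-chromatin interval (overlap = 0) joins that interval's promoter
    (nearest interval on ties of eligibility; exact distance ties go to the
    leftmost).  Remaining clusters are chained at <= ``max_dist`` bp into
    pseudo-promoters typed Closed200/Closed2000 by whether any open interval
    lies within ``closed_band`` bp of the group anchor.  The anchor is the
    mass center of the member with the highest baseline mean TPM (ties:
    5'-most position on the member's strand).

    Returns ``(promoters, members)``: a promoter table (promoter_id, chrom,
    start, end, ptype, bidirectional, anchor, n_members) and a member table
    (cluster_id -> promoter_id).
    """
    base_tpm = tpm[baseline_samples].mean(axis=1)
    cl = clusters.reset_index(drop=True)
    opens_by_chrom: dict[str, list] = {}
    for idx, iv in enumerate(open_intervals):
        opens_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))

    assigned: dict[int, list] = {}
    unassigned: list[int] = []
    for i, row in cl.iterrows():
        best = None
        for s, e, idx in opens_by_chrom.get(row.chrom, []):
            gap = _gap(row.start, row.end, s, e)
            if gap <= max_dist and (best is None or gap < best[0]
                                    or (gap == best[0] and s < best[1])):
                if best is not None and gap == best[0]:
                    log.info("cluster %s equidistant from two open intervals; "
                             "keeping leftmost", row.cluster_id)
                best = (gap, s, idx)
        if best is None:
            unassigned.append(i)
        else:
            assigned.setdefault(best[2], []).append(i)

    def anchor_of(member_idx):
        sub = cl.loc[member_idx]
        expr = base_tpm[sub["cluster_id"]].to_numpy()
        top = expr == expr.max()
        cand = sub[top]
        # 5'-most on the member's strand: min start on +, max end on -
        keys = [
            (r.start if r.strand == "+" else -r.end) for r in cand.itertuples()
        ]
        return cand.iloc[int(np.argmin(keys))]

    prom_rows, member_rows = [], []

    def add_promoter(chrom, start, end, ptype, member_idx):
        pid = f"prom_{len(prom_rows):05d}"
        sub = cl.loc[member_idx]
        top = anchor_of(member_idx)
        prom_rows.append(dict(
            promoter_id=pid, chrom=chrom, start=int(start), end=int(end),
            ptype=ptype,
            bidirectional=bool({"+", "-"} <= set(sub["strand"])),
            anchor=float(top.mass_center), anchor_cluster=top.cluster_id,
            n_members=len(member_idx),
        ))
        for cid in sub["cluster_id"]:
            member_rows.append(dict(cluster_id=cid, promoter_id=pid))

    for idx in sorted(assigned):
        iv = open_intervals[idx]
        add_promoter(iv.chrom, iv.start, iv.end, "Open", assigned[idx])

    # chain leftover clusters into pseudo-promoters at <= max_dist bp
    leftovers = cl.loc[unassigned].sort_values(["chrom", "start"])
    groups: list[list[int]] = []
    prev_chrom, prev_end = None, None
    for i, row in leftovers.iterrows():
        if prev_chrom == row.chrom and row.start - prev_end <= max_dist:
            groups[-1].append(i)
            prev_end = max(prev_end, row.end)
        else:
            groups.append([i])
            prev_end = row.end
        prev_chrom = row.chrom
    for member_idx in groups:
        sub = cl.loc[member_idx]
        chrom = sub["chrom"].iloc[0]
        start, end = int(sub["start"].min()), int(sub["end"].max())
        anchor = float(anchor_of(member_idx).mass_center)
        near_open = any(
            _gap(int(anchor), int(anchor) + 1, s, e) <= closed_band
            for s, e, _ in opens_by_chrom.get(chrom, [])
        )
        add_promoter(chrom, start, end, "Closed200" if near_open else "Closed2000",
                     member_idx)

    promoters = pd.DataFrame(prom_rows, columns=[
        "promoter_id", "chrom", "start", "end", "ptype", "bidirectional",
        "anchor", "anchor_cluster", "n_members",
    ])
    members = pd.DataFrame(member_rows, columns=["cluster_id", "promoter_id"])
    return promoters, members


def promoter_expression(counts: pd.DataFrame, members: pd.DataFrame) -> pd.DataFrame:
    """Per-sample promoter expression: sum over member clusters."""
    joined = counts.join(members.set_index("cluster_id"), how="inner")
    return joined.groupby("promoter_id").sum()


def tfbs_density(chip_sites: list[GenomicInterval], chrom: str, anchor: float,
                 window: int = 2000, bin_width: int = 10):
    """Binding-site density profile over [anchor-window, anchor+window).

    Site midpoints are binned at ``bin_width`` bp; each bin's density is
    sites per bp.  Returns ``(bin_edges_relative, density, max_density)``.
    """
    n_bins = (2 * window) // bin_width
    edges = np.arange(-window, window + bin_width, bin_width)
    lo = anchor - window
    counts = np.zeros(n_bins)
    for iv in chip_sites:
        if iv.chrom != chrom:
            continue
        mid = (iv.start + iv.end - 1) / 2
        b = int((mid - lo) // bin_width)
        if 0 <= b < n_bins:
            counts[b] += 1
    density = counts / bin_width
    return edges, density, float(density.max(initial=0.0))


def test_promoter_de(promoter_counts: pd.DataFrame, design: pd.DataFrame,
                     **kwargs) -> pd.DataFrame:
    """Differential promoter expression; same contract as differential.test_de."""
    from .differential import test_de

    return test_de(promoter_counts, design, **kwargs)
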