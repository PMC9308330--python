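"""Gene annotation of TSS clusters by a strict feature-priority scheme.

Each robust cluster is assigned a gene and a feature class by testing, in
order, whether its count mass center lies: within +/-``tss_window`` bp of an
annotated transcript TSS (class TSS) > inside a 5'UTR > 3'UTR > CDS > exon of
a non-protein-coding transcript > intron > intergenic.  The first satisfied
class wins; within a class the nearest feature's gene wins.  All tests are
strand-matched.  Putative novel TSSs (intron/intergenic clusters) can be
verified against RNA-seq splice-junction and coverage evidence, and clusters
that never reach 10% of their gene's top cluster are flagged minor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, GenomicInterval

TSS_WINDOW = 50
CLASSES = (
    "TSS", "UTR5", "UTR3", "CDS", "NC_EXON", "VERIFIED_NOVEL", "INTRON", "INTERGENIC",
)


def _feature_hits(mc, strand_feats, kind):
    """(gene_id, distance-to-feature) pairs for features containing mc."""
    hits = []
    for gene_id, intervals in strand_feats.get(kind, []):
        for s, e in intervals:
            if s <= mc < e:
                hits.append((gene_id, 0.0))
                break
    return hits


def annotate_clusters(clusters: pd.DataFrame, gene_models: list[GeneModel],
                      tss_window: int = TSS_WINDOW) -> pd.DataFrame:
    """Assign a gene and feature class to each cluster (priority scheme).

    ``clusters`` needs cluster_id, chrom, strand and mass_center columns.
    Returns a DataFrame with cluster_id, gene_id, feature_class and
    tss_distance (signed, strand-oriented: positive = downstream of the
    nearest annotated TSS).
    """
    # index features per (chrom, strand)
    by_cs: dict[tuple[str, str], dict] = {}
    for g in gene_models:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.gene_id} has unstranded annotation")
        d = by_cs.setdefault((g.chrom, g.strand), {
            "tss": [], "tss_gene": [], "utr5": [], "utr3": [], "cds": [],
            "nc_exon": [], "span": [],
        })
        for tx in g.transcripts:
            d["tss"].append(tx.tss)
            d["tss_gene"].append(g.gene_id)
            if tx.utr5:
                d["utr5"].append((g.gene_id, tx.utr5))
            if tx.utr3:
                d["utr3"].append((g.gene_id, tx.utr3))
            if tx.cds:
                d["cds"].append((g.gene_id, tx.cds))
            if not tx.coding:
                d["nc_exon"].append((g.gene_id, tx.exons))
            d["span"].append((g.gene_id, [tx.span]))
    for d in by_cs.values():
        d["tss_arr"] = np.asarray(d["tss"], dtype=float)

    records = []
    for row in clusters.itertuples(index=False):
        mc = row.mass_center
        d = by_cs.get((row.chrom, row.strand))
        gene_id, feature_class, tss_dist = None, "INTERGENIC", np.nan
        if d is not None and len(d["tss_arr"]):
            sign = 1.0 if row.strand == "+" else -1.0
            dists = (mc - d["tss_arr"]) * sign
            nearest = int(np.argmin(np.abs(dists)))
            tss_dist = float(dists[nearest])
            if abs(dists[nearest]) <= tss_window:
                gene_id, feature_class = d["tss_gene"][nearest], "TSS"
            else:
                for kind, cls in (
                    ("utr5", "UTR5"), ("utr3", "UTR3"), ("cds", "CDS"),
                    ("nc_exon", "NC_EXON"), ("span", "INTRON"),
                ):
                    hits = _feature_hits(mc, d, kind)
                    if hits:
                        gene_id, feature_class = hits[0][0], cls
                        break
        records.append(
            dict(cluster_id=row.cluster_id, gene_id=gene_id,
                 feature_class=feature_class, tss_distance=tss_dist)
        )
    return pd.DataFrame(records)


@dataclass
class JunctionEvidence:
    """Splice-donor intervals with read support plus strand-specific coverage."""

    donors: list[GenomicInterval]            # donor-site intervals, named by gene
    donor_reads: list[int]
    donor_genes: list[str]
    coverage: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    # coverage maps (chrom, strand) -> per-bp depth array


def verify_novel_tss(cluster_row, evidence: JunctionEvidence,
                     max_donor_dist: int = 2000, min_junction_reads: int = 5,
                     min_cov_fraction: float = 0.8):
    """Verify a putative novel TSS by junction + coverage evidence.

    The cluster is verified iff a same-strand splice donor lies within
    ``max_donor_dist`` bp downstream (strand-oriented) of its mass center with
    at least ``min_junction_reads`` supporting reads, and strand-specific
    coverage is positive over at least ``min_cov_fraction`` of the bases
    between the mass center and the donor.  Returns ``(verified, gene_id)``.
    """
    mc = cluster_row.mass_center
    chrom, strand = cluster_row.chrom, cluster_row.strand
    sign = 1 if strand == "+" else -1
    best = None
    for donor, reads, gene in zip(
        evidence.donors, evidence.donor_reads, evidence.donor_genes
    ):
        if donor.chrom != chrom or donor.strand != strand:
            continue
        donor_pos = donor.start if strand == "+" else donor.end - 1
        dist = (donor_pos - mc) * sign
        if 0 <= dist <= max_donor_dist and reads >= min_junction_reads:
            if best is None or dist < best[0]:
                best = (dist, donor_pos, gene)
    if best is None:
        return False, None
    _, donor_pos, gene = best
    cov = evidence.coverage.get((chrom, strand))
    lo, hi = int(min(mc, donor_pos)), int(max(mc, donor_pos)) + 1
    if cov is None:
        return False, None
    window = cov[lo:hi] if hi <= len(cov) else np.pad(cov[lo:], (0, hi - len(cov)))
    if len(window) == 0:
        return False, None
    if (window > 0).mean() >= min_cov_fraction:
        return True, gene
    return False, None


def flag_minor_clusters(annotation: pd.DataFrame, tpm: pd.DataFrame,
                        design: pd.DataFrame, fraction: float = 0.10,
                        mode: str = "major_if_ever") -> pd.Series:
    """Major/minor flags by the 10% rule.

    For every time point the per-cluster mean TPM across subjects is compared
    with the maximum over the gene's clusters at that time point.  Under the
    default ``mode="major_if_ever"`` a cluster is major if its ratio reaches
    ``fraction`` at some time point (minor = below the cutoff at every time
    point); ``mode="major_if_always"`` implements the opposite reading.
    Intron/intergenic clusters are exempt (always major/unflagged), as are
    clusters without a gene.

    Returns a boolean Series ``major`` indexed by cluster_id.
    """
    if mode not in ("major_if_ever", "major_if_always"):
        raise ValueError(f"unknown mode {mode!r}")
    mean_by_tp = {}
    for tp, sub in design.groupby("time"):
        mean_by_tp[tp] = tpm[sub.index.tolist()].mean(axis=1)
    ratios = pd.DataFrame(mean_by_tp)  # clusters x time points

    major = pd.Series(True, index=tpm.index, name="major")
    annot = annotation.set_index("cluster_id")
    exempt = annot["feature_class"].isin(("INTRON", "INTERGENIC")) | annot["gene_id"].isna()
    for gene, sub in annot[~exempt].groupby("gene_id"):
        ids = [c for c in sub.index if c in ratios.index]
        if not ids:
            continue
        r = ratios.loc[ids]
        frac_of_max = r / r.max(axis=0).replace(0, np.nan)
        reaches = (frac_of_max >= fraction).fillna(False)
        if mode == "major_if_ever":
            major.loc[ids] = reaches.any(axis=1)
        else:
            major.loc[ids] = reaches.all(axis=1)
    return major
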