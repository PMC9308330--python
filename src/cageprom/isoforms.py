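"""Canonical TSSs, removed alternative promoters, and alternative start codons.

The canonical TSS of a gene is its most highly expressed cluster at baseline.
An alternative promoter is "removed" when its region lies more than 200 bp
beyond the canonical promoter's region.  A gene is flagged as producing
alternative protein isoforms when the most-expressed TSS/5'UTR-class cluster
of at least two of its promoters links to transcripts with distinct annotated
start-codon positions (genomic first-base coordinate, strand-aware).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GeneModel

REMOVED_MIN_GAP = 200


def canonical_tss(gene_clusters: pd.DataFrame, baseline_mean_tpm: pd.Series) -> str:
    """Cluster with maximal baseline mean TPM; ties -> 5'-most on gene strand."""
    if not len(gene_clusters):
        raise ValueError("gene has no clusters")
    expr = baseline_mean_tpm[gene_clusters["cluster_id"]].to_numpy()
    top = gene_clusters[expr == expr.max()]
    keys = [r.start if r.strand == "+" else -r.end for r in top.itertuples()]
    return str(top.iloc[int(np.argmin(keys))]["cluster_id"])


def removed_alt_promoters(gene_promoters: pd.DataFrame, canonical_promoter: str,
                          min_gap: int = REMOVED_MIN_GAP) -> pd.Series:
    """Removed flag per alternative promoter: region gap strictly > min_gap bp."""
    prom = gene_promoters.set_index("promoter_id")
    canon = prom.loc[canonical_promoter]
    flags = {}
    for pid, row in prom.iterrows():
        if pid == canonical_promoter:
            flags[pid] = False
            continue
        gap = max(0, max(row.start, canon.start) - min(row.end, canon.end))
        flags[pid] = bool(gap > min_gap)
    return pd.Series(flags, name="removed")


def alt_start_codons(gene_id: str, promoter_members: pd.DataFrame,
                     clusters: pd.DataFrame, annotation: pd.DataFrame,
                     gene_model: GeneModel, baseline_mean_tpm: pd.Series,
                     tss_window: int = 50):
    """Alternative-start-codon call for one gene.

    For each promoter of the gene, the most-expressed member cluster of class
    TSS or UTR5 links to transcripts whose annotated TSS is within
    +/-``tss_window`` bp of the cluster anchor or whose 5'UTR contains the
    anchor; the linked transcripts' start-codon first-base positions are
    collected.  Returns ``(flagged, codon_map, skipped_promoters)`` where
    ``codon_map`` maps promoter_id -> sorted start-codon positions and the
    gene is flagged iff >= 2 distinct positions occur across promoters.
    """
    annot = annotation.set_index("cluster_id")
    cl = clusters.set_index("cluster_id")
    codon_map: dict[str, list[int]] = {}
    skipped: list[str] = []
    for pid, sub in promoter_members.groupby("promoter_id"):
        ids = [c for c in sub["cluster_id"]
               if c in annot.index and annot.loc[c, "gene_id"] == gene_id]
        if not ids:
            continue
        expr = baseline_mean_tpm[ids]
        top_id = expr.idxmax()
        if annot.loc[top_id, "feature_class"] not in ("TSS", "UTR5"):
            skipped.append(pid)
            continue
        anchor = cl.loc[top_id, "mass_center"]
        codons = set()
        for tx in gene_model.transcripts:
            linked = abs(tx.tss - anchor) <= tss_window or any(
                s <= anchor < e for s, e in tx.utr5
            )
            if linked and tx.start_codon is not None:
                codons.add(int(tx.start_codon))
        codon_map[pid] = sorted(codons)
    distinct = {c for codons in codon_map.values() for c in codons}
    return len(distinct) >= 2, codon_map, skipped


def call_isoforms(annotation: pd.DataFrame, clusters: pd.DataFrame,
                  promoters: pd.DataFrame, members: pd.DataFrame,
                  gene_models: list[GeneModel], tpm: pd.DataFrame,
                  baseline_samples: list[str], min_gap: int = REMOVED_MIN_GAP,
                  tss_window: int = 50) -> pd.DataFrame:
    """Per-gene isoform calls over the whole study.

    Returns one row per gene with >= 1 robust cluster: canonical cluster,
    number of promoters, number of removed alternative promoters, and the
    alternative-start-codon flag.
    """
    base_tpm = tpm[baseline_samples].mean(axis=1)
    cl = clusters.merge(annotation[["cluster_id", "gene_id"]], on="cluster_id")
    member_prom = members.set_index("cluster_id")["promoter_id"]
    prom = promoters.set_index("promoter_id")
    models = {g.gene_id: g for g in gene_models}
    rows = []
    for gene, sub in cl.dropna(subset=["gene_id"]).groupby("gene_id"):
        canon_cluster = canonical_tss(sub, base_tpm)
        pids = sorted({member_prom[c] for c in sub["cluster_id"]
                       if c in member_prom.index})
        gene_prom = prom.loc[pids].reset_index()
        canon_prom = member_prom.get(canon_cluster)
        n_removed = 0
        if canon_prom in pids and len(pids) > 1:
            removed = removed_alt_promoters(gene_prom, canon_prom, min_gap)
            n_removed = int(removed.sum())
        flagged, codon_map, skipped = alt_start_codons(
            gene, members[members["promoter_id"].isin(pids)], clusters,
            annotation, models[gene], base_tpm, tss_window,
        ) if gene in models else (False, {}, [])
        rows.append(dict(
            gene_id=gene, canonical_cluster=canon_cluster,
            canonical_promoter=canon_prom, n_promoters=len(pids),
            n_removed_alt_promoters=n_removed,
            alt_start_codons=bool(flagged),
            n_start_codons=len({c for v in codon_map.values() for c in v}),
        ))
    return pd.DataFrame(rows)
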