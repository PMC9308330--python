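"""End-to-end orchestration of the promoter-usage analysis on one study.

Chains every stage on in-memory study inputs: tag clustering ->
quantification -> robust filter -> gene annotation -> minor-cluster flags ->
gene-level differential expression -> differential TSS usage -> consensus
open chromatin -> promoter assignment -> promoter differential expression ->
TFBS enrichment of DE promoters vs non-DE promoters -> rank-profile CRC
clustering of DE promoters -> isoform calls.  Used by the examples and the
acceptance script; each stage remains callable on its own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import annotation as ann
from . import clustering, crc, differential, isoforms, motifs, promoters


def extract_sequences(genome: dict[str, str], regions: pd.DataFrame,
                      pad: int = 0) -> dict[str, str]:
    """Promoter sequences (forward strand) for a promoter table."""
    out = {}
    for row in regions.itertuples():
        seq = genome[row.chrom]
        lo, hi = max(0, row.start - pad), min(len(seq), row.end + pad)
        out[row.promoter_id] = seq[lo:hi]
    return out


def run_study(study: dict, max_gap: int = 20, tss_window: int = 50,
              crc_processes: int = 10, crc_cycles: int = 50,
              crc_seed: int = 0, non_de_padj: float = 0.4,
              max_background: int = 5000, min_background_bp: int = 100_000,
              with_enrichment: bool = True, with_crc: bool = True) -> dict:
    """Run the full pipeline on a generated (or loaded) study dict.

    ``study`` needs tag_table, design, gene_models, open_chromatin,
    chip_sites; genome is required for the enrichment stage.  Returns a dict
    of stage outputs keyed by stage name.
    """
    design = study["design"]
    truth = study.get("truth")
    cfg = truth.config if truth is not None else None
    baseline = cfg.baseline if cfg is not None else "pre"
    exclude = tuple(cfg.excluded_time_points) if cfg is not None else ("2min",)

    clusters, counts = clustering.cluster_tags(study["tag_table"], max_gap=max_gap)
    library_sizes = counts.sum(axis=0)
    tpm = clustering.quantify(counts, library_sizes)
    robust = clustering.filter_robust(counts, tpm)
    rclusters = clusters[robust.loc[clusters["cluster_id"]].to_numpy()].reset_index(drop=True)
    rcounts, rtpm = counts.loc[rclusters["cluster_id"]], tpm.loc[rclusters["cluster_id"]]

    annot = ann.annotate_clusters(rclusters, study["gene_models"], tss_window)
    major = ann.flag_minor_clusters(annot, rtpm, design)

    gene_counts = (
        rcounts.join(annot.set_index("cluster_id")["gene_id"])
        .dropna(subset=["gene_id"]).groupby("gene_id").sum()
    )
    de = differential.test_de(gene_counts, design, baseline=baseline,
                              exclude=exclude)
    dtu = differential.test_dtu(rcounts, annot, design, baseline=baseline,
                                exclude=exclude)

    chromatin = study["open_chromatin"]
    consensus = promoters.consensus_open_chromatin(
        chromatin["atac"], chromatin["dnase"]
    )
    baseline_samples = design[design["time"] == baseline].index.tolist()
    proms, members = promoters.assign_promoters(
        consensus, rclusters, rtpm, baseline_samples
    )
    prom_counts = promoters.promoter_expression(rcounts, members)
    prom_de = promoters.test_promoter_de(prom_counts, design,
                                         baseline=baseline, exclude=exclude)

    out = dict(
        clusters=clusters, counts=counts, tpm=tpm, robust=robust,
        robust_clusters=rclusters, annotation=annot, major=major,
        gene_counts=gene_counts, de=de, dtu=dtu,
        consensus_open=consensus, promoters=proms, members=members,
        promoter_counts=prom_counts, promoter_de=prom_de,
    )

    # promoter sets for enrichment: DE foreground vs never-DE background
    de_wide = prom_de.pivot(index="unit_id", columns="time", values="deg")
    padj_wide = prom_de.pivot(index="unit_id", columns="time", values="padj")
    fg_ids = de_wide.index[de_wide.any(axis=1)].tolist()
    bg_ids = padj_wide.index[(padj_wide > non_de_padj).all(axis=1)].tolist()
    bg_ids = [i for i in bg_ids if i not in set(fg_ids)][:max_background]
    out["foreground_ids"], out["background_ids"] = fg_ids, bg_ids

    if with_enrichment and study.get("genome") is not None and fg_ids and bg_ids:
        pidx = proms.set_index("promoter_id")
        fg = extract_sequences(study["genome"], pidx.loc[fg_ids].reset_index())
        bg = extract_sequences(study["genome"], pidx.loc[bg_ids].reset_index())
        pwms = truth.pwms if truth is not None else study["pwms"]
        try:
            enr, per_tf = motifs.enrich(fg, bg, pwms,
                                        min_background_bp=min_background_bp)
            out["enrichment"], out["enrichment_per_tf"] = enr, per_tf
        except ValueError:
            out["enrichment"] = out["enrichment_per_tf"] = None

    if with_crc and fg_ids:
        tps = [t for t in pd.unique(design["time"]) if t not in exclude]
        dsub = design[design["time"].isin(tps)]
        ranks = crc.rank_profiles(prom_counts.loc[fg_ids], dsub, time_order=tps)
        out["crc"] = crc.crc_cluster(ranks, n_processes=crc_processes,
                                     n_cycles=crc_cycles, seed=crc_seed)

    out["isoforms"] = isoforms.call_isoforms(
        annot, rclusters, proms, members, study["gene_models"], rtpm,
        baseline_samples,
    )
    return out


def score_against_truth(result: dict, truth) -> dict:
    """Recovery metrics of a pipeline run against the planted truth.

    Maps each robust cluster to the nearest planted TSS of its strand and
    scores annotation classes, promoter types, DE/DTU recovery and the
    alternative-start-codon calls.  Returns a flat dict of rates and counts.
    """
    rcl = result["robust_clusters"]
    tss = truth.tss
    # nearest planted TSS per cluster (same strand)
    cluster_tss = {}
    for strand in ("+", "-"):
        t = tss[tss["strand"] == strand]
        c = rcl[rcl["strand"] == strand]
        if not len(t) or not len(c):
            continue
        tpos = t["pos"].to_numpy()
        order = np.argsort(tpos)
        for row in c.itertuples():
            j = np.searchsorted(tpos[order], row.mass_center)
            cand = [k for k in (j - 1, j) if 0 <= k < len(order)]
            best = min(cand, key=lambda k: abs(tpos[order[k]] - row.mass_center))
            cluster_tss[row.cluster_id] = t.iloc[order[best]]

    annot = result["annotation"].set_index("cluster_id")
    # annotation-class recovery among clusters within the TSS window
    within = {cid: t for cid, t in cluster_tss.items()
              if abs(float(rcl.set_index("cluster_id").loc[cid, "mass_center"])
                     - t["pos"]) <= 50}
    ann_ok = np.mean([
        annot.loc[cid, "feature_class"] == "TSS"
        and annot.loc[cid, "gene_id"] == t["gene_id"]
        for cid, t in within.items()
    ]) if within else np.nan

    members = result["members"].set_index("cluster_id")["promoter_id"]
    ptype = result["promoters"].set_index("promoter_id")["ptype"]
    type_pairs = [
        (t["open_status"], ptype[members[cid]])
        for cid, t in cluster_tss.items() if cid in members.index
    ]
    type_ok = np.mean([a == b for a, b in type_pairs]) if type_pairs else np.nan
    confusion = pd.crosstab(
        pd.Series([a for a, _ in type_pairs], name="truth"),
        pd.Series([b for _, b in type_pairs], name="called"),
    )

    genes = truth.genes.set_index("gene_id")
    de_wide = result["de"].pivot(index="unit_id", columns="time", values="deg")
    called_de = de_wide.any(axis=1)
    de_truth = genes["de"]
    common = called_de.index.intersection(de_truth.index)
    tp = (called_de[common] & de_truth[common]).sum()
    de_sens = tp / de_truth[common].sum() if de_truth[common].sum() else np.nan
    fp = (called_de[common] & ~de_truth[common]).sum()
    de_fdp = fp / max(1, called_de[common].sum())

    dtu_wide = result["dtu"].pivot(index="gene_id", columns="time", values="dtu")
    called_dtu = dtu_wide.any(axis=1)
    dtu_truth = genes["dtu"]
    common_d = called_dtu.index.intersection(dtu_truth.index)
    dtu_sens = (
        (called_dtu[common_d] & dtu_truth[common_d]).sum()
        / dtu_truth[common_d].sum()
    ) if dtu_truth[common_d].sum() else np.nan

    iso = result["isoforms"].set_index("gene_id")
    alt_truth = genes["alt_codon"]
    common_i = iso.index.intersection(alt_truth.index)
    alt_called = iso.loc[common_i, "alt_start_codons"]
    alt_sens = (
        (alt_called & alt_truth[common_i]).sum() / alt_truth[common_i].sum()
    ) if alt_truth[common_i].sum() else np.nan
    alt_fp = int((alt_called & ~alt_truth[common_i]).sum())

    return dict(
        n_clusters=len(result["clusters"]), n_robust=len(rcl),
        annotation_tss_accuracy=float(ann_ok),
        promoter_type_accuracy=float(type_ok),
        promoter_type_confusion=confusion,
        de_sensitivity=float(de_sens), de_false_discovery=float(de_fdp),
        dtu_sensitivity=float(dtu_sens),
        alt_codon_sensitivity=float(alt_sens),
        alt_codon_false_positives=alt_fp,
    )
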