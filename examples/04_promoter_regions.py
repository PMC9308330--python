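"""Build individual promoter regions from replicated open-chromatin peaks.

Replicates are merged within each assay, ATAC and DNase tracks intersected,
intervals < 71 bp apart joined; TSS clusters within 200 bp of a consensus
interval form Open promoters, the rest chain into Closed200 / Closed2000
pseudo-promoters; the binding-site density profile around each promoter
anchor is computed from ChIP-seq-like site intervals.
"""

import numpy as np

from cageprom import clustering, promoters
from cageprom.simulate import SyntheticConfig, generate_study

study = generate_study(SyntheticConfig(seed=1, n_genes=100),
                       with_sequence=False)

clusters, counts = clustering.cluster_tags(study["tag_table"])
tpm = clustering.quantify(counts, counts.sum(axis=0))
robust = clustering.filter_robust(counts, tpm)
rclusters = clusters[robust.to_numpy()].reset_index(drop=True)

consensus = promoters.consensus_open_chromatin(
    study["open_chromatin"]["atac"], study["open_chromatin"]["dnase"]
)
baseline = study["design"][study["design"]["time"] == "pre"].index.tolist()
proms, members = promoters.assign_promoters(consensus, rclusters,
                                            tpm.loc[rclusters["cluster_id"]],
                                            baseline)

print(f"consensus open intervals: {len(consensus)}")
print("promoter types:", proms["ptype"].value_counts().to_dict())
print(f"bidirectional promoters: {proms['bidirectional'].sum()}")

# average TFBS density profile across Open promoters, oriented by the
# anchor cluster's strand so 'upstream' means the same thing for every gene
strand_of = rclusters.set_index("cluster_id")["strand"]
profiles = []
for row in proms[proms["ptype"] == "Open"].itertuples():
    edges, dens, _ = promoters.tfbs_density(study["chip_sites"], row.chrom,
                                            row.anchor)
    profiles.append(dens if strand_of[row.anchor_cluster] == "+" else dens[::-1])
mean_profile = np.mean(profiles, axis=0)
centers = np.arange(-2000, 2000, 10) + 5
# restrict to +/-1 kb: beyond that the window reaches the site clouds of a
# gene's *other* alternative promoters (2.2 kb away)
core = np.abs(centers) <= 1000
mean_offset = (mean_profile[core] * centers[core]).sum() / mean_profile[core].sum()
print(f"density-weighted mean TFBS position (+/-1 kb core): "
      f"{mean_offset:+.0f} bp from the promoter anchor")
print("Negative offsets are upstream of the most-expressed TSS cluster: the")
print("binding-site density concentrates just upstream, as open chromatin does.")
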