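"""PWM-based TFBS enrichment in differentially regulated promoters.

Each position weight matrix gets a log2-odds cutoff calibrated on the
background promoters (site frequency at most 1 per 2000 bp), both promoter
sets are scanned on both strands, and enrichment is scored as a site-rate
ratio (binomial test) and a promoter-hit odds ratio (Fisher exact test),
each with a 99%-CI-adjusted fold enrichment FE_adj.  A matrix is enriched
when FE_adj > 1.5 at FDR < 0.05.
"""

from cageprom.motifs import enrich
from cageprom.pipeline import run_study
from cageprom.simulate import SyntheticConfig, generate_study

study = generate_study(SyntheticConfig(seed=1, n_genes=200))
result = run_study(study, with_crc=False, min_background_bp=50_000)

enr = result["enrichment"]
cols = ["matrix_id", "tf_name", "sites_fg", "sites_bg", "fe_site",
        "fe_adj_site", "fdr_site", "enriched"]
print(f"foreground (DE) promoters: {len(result['foreground_ids'])}, "
      f"background (never-DE): {len(result['background_ids'])}")
print(enr.sort_values("fe_adj_site", ascending=False)[cols]
      .to_string(index=False))
print("The generator plants the M_STRESS1 consensus upstream of DE genes'")
print("canonical TSSs, so that matrix should be the only enriched one: its")
print("binding sites occur several-fold more often per bp in DE promoters.")
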