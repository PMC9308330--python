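"""Generate a synthetic acute-stress CAGE study and write it to disk.

Builds a 100-gene study (10 subjects x 4 time points) with planted
differential expression, differential TSS usage, open-chromatin peaks and
promoter motifs, then writes genome FASTA, annotation GTF, peak BEDs and the
tag-count table under scratch/study/ and reloads them through the package's
own readers.
"""

from pathlib import Path

from cageprom import io
from cageprom.simulate import SyntheticConfig, generate_study

out = Path("scratch/study")
out.mkdir(parents=True, exist_ok=True)

cfg = SyntheticConfig(seed=1, n_genes=100)
cfg.to_yaml(out / "config.yaml")
study = generate_study(cfg)

io.write_fasta(study["genome"], out / "genome.fa")
io.write_gtf(study["gene_models"], out / "annotation.gtf")
io.write_table(study["tag_table"], out / "cage_tags.tsv")
io.write_table(study["design"].reset_index(names="sample"), out / "design.tsv")
for assay, reps in study["open_chromatin"].items():
    for r, peaks in enumerate(reps):
        io.write_bed(peaks, out / f"{assay}_rep{r}.bed")
io.write_bed(study["chip_sites"], out / "chip_sites.bed")
io.write_table(study["truth"].genes, out / "truth_genes.tsv")
io.write_table(study["truth"].tss, out / "truth_tss.tsv")

# round-trip sanity: the emitted formats are exactly what the readers consume
genome = io.read_fasta(out / "genome.fa")
models = io.read_gtf(out / "annotation.gtf")
tags = io.read_tag_table(out / "cage_tags.tsv")
peaks = io.read_bed(out / "atac_rep0.bed")

truth = study["truth"]
print(f"genome: {len(genome[cfg.chrom]):,} bp on {cfg.chrom}")
print(f"genes: {len(models)} ({truth.genes['de'].sum()} DE, "
      f"{truth.genes['dtu'].sum()} DTU, "
      f"{(truth.genes['open_status'] != 'Open').sum()} with closed chromatin)")
print(f"tag table: {len(tags)} positions x {len(study['design'])} samples")
print(f"ATAC rep0: {len(peaks)} peaks; planted motifs: {len(truth.motifs)}")
print("A DE gene carries a fold change at every post-stress time point; a DTU")
print("gene swaps its TSS proportions; truth tables record both for scoring.")
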