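"""Self-consistent synthetic acute-stress CAGE study with recorded ground truth.

Emulates, at desk scale, a stranded CAGE time-course over multi-TSS gene
models: a random genome with non-overlapping genes (one slot per gene), 1-3
TSSs per gene spaced far enough apart to create removed alternative
promoters, negative-binomial tag counts for n_subjects x time_points with a
paired (subject x gene) log-normal effect, planted differential expression
(fold changes) and differential TSS usage (proportion swaps), replicated
open-chromatin peaks whose mass is shifted upstream of each open TSS (with
Closed200 / Closed2000 genes carrying banded or no open chromatin),
TSS-proximal ChIP-seq site density, and transcription-factor motif
consensus strings written into responsive promoter sequences.

Every output is regenerable byte-identically from (config, seed), and the
truth tables are sufficient to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import (
    GeneModel, GenomicInterval, PWMRecord, Transcript, revcomp,
)

TSS_OFFSETS = (0, 2200, 4400)  # local offsets of alternative TSSs within a gene


def default_pwms() -> list[PWMRecord]:
    """A small built-in PWM collection (distinct 10-bp consensus motifs)."""
    specs = [
        ("M_STRESS1", "STF1", "TGACGTCATC"),
        ("M_STRESS2", "STF2", "GGAAGTGAAC"),
        ("M_HOUSE1", "HKF1", "CCGTTAGCGG"),
        ("M_HOUSE2", "HKF2", "ATCGATACGT"),
        ("M_MYO1", "MYF1", "CAGCTGTTGG"),
        ("M_MYO2", "MYF2", "TTAGGCCTAA"),
    ]
    pwms = []
    for mid, tf, consensus in specs:
        counts = np.ones((len(consensus), 4))
        for j, b in enumerate(consensus):
            counts[j, "ACGT".index(b)] = 17.0
        pwms.append(PWMRecord(mid, tf, counts))
    return pwms


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated design: 10 subjects sampled before and 1, 3
    and 6 h after acute stress (an optional early 2-min point can be
    generated but is excluded from differential stages), ~200k tags per
    library, overdispersed (negative binomial) counts with a paired
    subject-by-gene effect, and 10% each of genes carrying planted fold
    changes or TSS-proportion swaps.
    """

    seed: int = 0
    n_genes: int = 200
    n_subjects: int = 10
    time_points: tuple = ("pre", "1h", "3h", "6h")
    excluded_time_points: tuple = ()      # e.g. ("2min",), generated, never tested
    baseline: str = "pre"
    tss_per_gene_probs: tuple = (0.4, 0.4, 0.2)   # P(1), P(2), P(3) TSSs
    library_size: int = 200_000
    nb_dispersion: float = 0.1
    subject_sd: float = 0.4
    de_fraction: float = 0.10
    log2fc_range: tuple = (1.0, 2.0)
    dtu_fraction: float = 0.10
    closed200_fraction: float = 0.05
    closed2000_fraction: float = 0.05
    noncoding_fraction: float = 0.10
    alt_codon_fraction: float = 0.5
    broad_fraction: float = 0.5
    baseline_props: dict | None = None    # k -> proportion tuple; default below
    motif_plant_rate: float = 0.8
    planted_motif: str = "M_STRESS1"
    peak_width: int = 800
    peak_shift: int = -150                # strand-oriented; negative = upstream
    peak_jitter: int = 50
    n_replicates: int = 2
    band_peak_offset: int = -1000         # Closed200 band peak, strand-oriented
    band_peak_width: int = 600
    chip_n_sites: int = 5000
    chip_promoter_weight: float = 0.7
    chip_offset_mean: float = -150.0
    chip_offset_sd: float = 300.0
    chip_site_width: int = 15
    slot_len: int = 12_000
    chrom: str = "chr1"

    def __post_init__(self):
        for name in ("de_fraction", "dtu_fraction", "closed200_fraction",
                     "closed2000_fraction", "noncoding_fraction",
                     "alt_codon_fraction", "broad_fraction", "motif_plant_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if len(self.time_points) < 2:
            raise ValueError("need at least 2 time points")
        if self.closed200_fraction + self.closed2000_fraction > 1:
            raise ValueError("closed fractions sum above 1")
        self.time_points = tuple(self.time_points)
        self.excluded_time_points = tuple(self.excluded_time_points)
        self.tss_per_gene_probs = tuple(self.tss_per_gene_probs)
        self.log2fc_range = tuple(self.log2fc_range)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @property
    def genome_length(self) -> int:
        return self.slot_len * (self.n_genes + 1)


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery scoring."""

    config: SyntheticConfig
    genes: pd.DataFrame      # gene_id, strand, k, de, fold_change, dtu, ...
    tss: pd.DataFrame        # gene_id, tss_id, pos, strand, props, status, shape
    motifs: pd.DataFrame     # gene_id, matrix_id, pos
    pwms: list[PWMRecord] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.config.chrom


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


_BASELINE_PROPS = {1: (1.0,), 2: (0.7, 0.3), 3: (0.55, 0.3, 0.15)}


def _flip(slot_start, slot_len, a, b):
    """Mirror interval [a, b) within its gene slot (minus-strand layout)."""
    return (2 * slot_start + slot_len - b, 2 * slot_start + slot_len - a)


def generate_genome(config: SyntheticConfig, with_sequence: bool = True):
    """Genome sequence, gene models and the truth skeleton.

    Returns ``(genome, gene_models, truth)``; ``genome`` is a dict
    chrom -> sequence (or None when ``with_sequence`` is False, for stages
    that only need counts).  Genes are laid out one per ``slot_len`` window
    so that planted Closed2000 promoters cannot be contaminated by a
    neighbouring gene's peaks.
    """
    if config.genome_length < config.slot_len * (config.n_genes + 1):
        raise ValueError("genome too small to place all genes")
    rng = _rng(config, 0)
    pwms = default_pwms()
    pwm_by_id = {p.matrix_id: p for p in pwms}
    if config.planted_motif not in pwm_by_id:
        raise ValueError(f"unknown planted motif {config.planted_motif}")

    n = config.n_genes
    k_per_gene = rng.choice(
        np.arange(1, len(config.tss_per_gene_probs) + 1), size=n,
        p=np.asarray(config.tss_per_gene_probs) / sum(config.tss_per_gene_probs),
    )
    strands = rng.choice(["+", "-"], size=n)
    de = rng.random(n) < config.de_fraction
    lfc = rng.uniform(*config.log2fc_range, size=n)
    sign = rng.choice([1.0, -1.0], size=n)
    fold_change = np.where(de, 2.0 ** (lfc * sign), 1.0)
    dtu = (rng.random(n) < config.dtu_fraction) & (k_per_gene >= 2)
    u = rng.random(n)
    status = np.where(
        u < config.closed2000_fraction, "Closed2000",
        np.where(u < config.closed2000_fraction + config.closed200_fraction,
                 "Closed200", "Open"),
    )
    noncoding = rng.random(n) < config.noncoding_fraction
    alt_codon = (rng.random(n) < config.alt_codon_fraction) & (k_per_gene >= 2) \
        & ~noncoding

    gene_rows, tss_rows, motif_rows = [], [], []
    gene_models = []
    planted = []  # (genomic pos, sequence-to-write)

    span = 7000  # bp a gene's features occupy within its slot
    for g in range(n):
        gid = f"G{g:04d}"
        o = config.slot_len * g + 2000  # gene occupies [o, o + span)
        strand = strands[g]
        k = int(k_per_gene[g])
        offsets = TSS_OFFSETS[:k]
        exon2 = (o + 6000, o + 7000)
        model = GeneModel(gid, config.chrom, strand)
        local = []
        for j, off in enumerate(offsets):
            t0 = o + off
            exon1 = (t0, t0 + 150)
            if noncoding[g]:
                cds, codon = [], None
            elif alt_codon[g]:
                cds, codon = [(t0 + 50, t0 + 150), (o + 6000, o + 6800)], t0 + 50
            else:
                cds, codon = [(o + 6100, o + 6800)], o + 6100
            local.append((f"{gid}.T{j}", t0, [exon1, exon2], cds, codon))
        for tid, t0, exons, cds, codon in local:
            if strand == "+":
                tx = Transcript(tid, t0, sorted(exons), cds=sorted(cds),
                                start_codon=codon)
            else:
                f_ex = sorted(_flip(o, span, a, b) for a, b in exons)
                f_cds = sorted(_flip(o, span, a, b) for a, b in cds)
                f_tss = f_ex[-1][1] - 1
                f_codon = None if codon is None else (
                    _flip(o, span, codon, codon + 1)[1] - 1
                )
                tx = Transcript(tid, f_tss, f_ex, cds=f_cds, start_codon=f_codon)
            # derive UTRs from exon/CDS structure
            if tx.cds:
                lo, hi = tx.cds[0][0], tx.cds[-1][1]
                before = [(s, min(e, lo)) for s, e in tx.exons if s < lo]
                after = [(max(s, hi), e) for s, e in tx.exons if e > hi]
                tx.utr5, tx.utr3 = (before, after) if strand == "+" else (after, before)
            model.transcripts.append(tx)
        gene_models.append(model)
        props = (config.baseline_props or _BASELINE_PROPS)[k]
        widths = rng.integers(30, 81, size=k)
        broad = rng.random(k) < config.broad_fraction
        for j, tx in enumerate(model.transcripts):
            tss_rows.append(dict(
                gene_id=gid, tss_id=f"{gid}.tss{j}", pos=int(tx.tss),
                strand=strand, baseline_prop=props[j],
                open_status=status[g],
                shape="broad" if broad[j] else "sharp",
                width=int(widths[j]),
            ))
        canonical_pos = int(model.transcripts[0].tss)
        gene_rows.append(dict(
            gene_id=gid, strand=strand, k=k, de=bool(de[g]),
            fold_change=float(fold_change[g]), dtu=bool(dtu[g]),
            open_status=status[g], coding=not bool(noncoding[g]),
            alt_codon=bool(alt_codon[g]), canonical_pos=canonical_pos,
        ))
        # plant the responsive motif upstream of each DE gene's canonical TSS
        if de[g] and rng.random() < config.motif_plant_rate:
            cons = pwm_by_id[config.planted_motif].consensus
            L = len(cons)
            if strand == "+":
                p = int(rng.integers(canonical_pos - 400, canonical_pos - 20 - L))
                planted.append((p, cons))
            else:
                p = int(rng.integers(canonical_pos + 20, canonical_pos + 400 - L))
                planted.append((p, revcomp(cons)))
            motif_rows.append(dict(gene_id=gid, matrix_id=config.planted_motif,
                                   pos=p))

    genome = None
    if with_sequence:
        seq = rng.integers(0, 4, size=config.genome_length, dtype=np.int8)
        arr = np.frombuffer(b"ACGT", dtype=np.uint8)[seq].copy()
        for p, s in planted:
            arr[p:p + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
        genome = {config.chrom: arr.tobytes().decode("ascii")}

    truth = SyntheticTruth(
        config=config,
        genes=pd.DataFrame(gene_rows),
        tss=pd.DataFrame(tss_rows),
        motifs=pd.DataFrame(motif_rows, columns=["gene_id", "matrix_id", "pos"]),
        pwms=pwms,
    )
    return genome, gene_models, truth


def make_design(config: SyntheticConfig) -> pd.DataFrame:
    """Sample sheet: index = sample name, columns subject and time."""
    rows = {}
    tps = list(config.time_points) + [
        t for t in config.excluded_time_points if t not in config.time_points
    ]
    for i in range(config.n_subjects):
        for t in tps:
            rows[f"S{i:02d}_{t}"] = dict(subject=f"S{i:02d}", time=t)
    return pd.DataFrame.from_dict(rows, orient="index")


def _offset_probs(shape: str, width: int):
    """Per-position tag probabilities around a TSS (sharp vs broad class)."""
    if shape == "sharp":
        offsets = np.arange(-5, 6)
        p = 0.5 ** np.abs(offsets)
    else:
        half = width // 2
        offsets = np.arange(-half, width - half)
        p = np.ones_like(offsets, dtype=float)
    return offsets, p / p.sum()


def generate_cage_counts(truth: SyntheticTruth, config: SyntheticConfig | None = None):
    """Per-sample CAGE tag tables with planted DE/DTU effects.

    Expected cluster count = library_size x gene abundance x TSS proportion x
    subject effect x time-point fold change, drawn negative-binomially
    (gamma-Poisson, shared dispersion) and spread over a positional window
    around the true TSS.  Returns ``(tag_table, design)``.
    """
    config = config or truth.config
    rng = _rng(config, 1)
    design = make_design(config)
    genes = truth.genes
    n = len(genes)
    abundance = rng.lognormal(0.0, 0.8, size=n)
    abundance /= abundance.sum()
    subj_effect = rng.lognormal(0.0, config.subject_sd,
                                size=(n, config.n_subjects))
    tested_tps = [t for t in config.time_points if t != config.baseline]

    tss = truth.tss
    frames = []
    gene_index = {gid: i for i, gid in enumerate(genes["gene_id"])}
    for gid, sub in tss.groupby("gene_id", sort=True):
        gi = gene_index[gid]
        grow = genes.iloc[gi]
        props_base = sub["baseline_prop"].to_numpy()
        props_shift = props_base[::-1] if grow["dtu"] else props_base
        pos_blocks, count_blocks = [], []
        for j, trow in enumerate(sub.itertuples()):
            offsets, op = _offset_probs(trow.shape, trow.width)
            positions = trow.pos + offsets
            block = np.zeros((len(positions), len(design)), dtype=np.int64)
            for s_idx, (sample, d) in enumerate(design.iterrows()):
                subj_i = int(d["subject"][1:])
                tp = d["time"]
                prop = props_base[j] if tp == config.baseline else props_shift[j]
                fc = grow["fold_change"] if (
                    grow["de"] and tp in tested_tps
                ) else 1.0
                if tp == config.baseline or tp in config.excluded_time_points:
                    fc = 1.0
                    prop = props_base[j]
                mean = (config.library_size * abundance[gi]
                        * subj_effect[gi, subj_i] * fc * prop)
                if mean <= 0:
                    continue
                disp = config.nb_dispersion
                lam = mean if disp <= 0 else rng.gamma(1.0 / disp, disp * mean)
                total = rng.poisson(lam)
                if total > 0:
                    block[:, s_idx] = rng.multinomial(total, op)
            pos_blocks.append(positions)
            count_blocks.append(block)
        frame = pd.DataFrame(np.vstack(count_blocks), columns=design.index)
        frame.insert(0, "chrom", config.chrom)
        frame.insert(1, "pos", np.concatenate(pos_blocks))
        frame.insert(2, "strand", grow["strand"])
        frames.append(frame)
    tag_table = pd.concat(frames, ignore_index=True)
    tag_table = tag_table[tag_table[design.index].sum(axis=1) > 0].reset_index(
        drop=True
    )
    return tag_table, design


def generate_open_chromatin(truth: SyntheticTruth,
                            config: SyntheticConfig | None = None):
    """Replicated ATAC-like and DNase-like peak BED sets around open TSSs.

    Open TSSs get a peak covering the TSS with its mass shifted upstream
    (strand-oriented ``peak_shift``); Closed200 genes get peaks only in the
    200-2000 bp band; Closed2000 genes get no peak within 2 kb.  Returns
    ``{"atac": [replicates...], "dnase": [replicates...]}``.
    """
    config = config or truth.config
    rng = _rng(config, 2)
    assays = {}
    for assay in ("atac", "dnase"):
        reps = []
        for rep in range(config.n_replicates):
            peaks = []
            for trow in truth.tss.itertuples():
                sign = 1 if trow.strand == "+" else -1
                jitter = int(rng.integers(-config.peak_jitter,
                                          config.peak_jitter + 1))
                if trow.open_status == "Open":
                    center = trow.pos + sign * config.peak_shift + jitter
                    half = config.peak_width // 2
                    peaks.append(GenomicInterval(
                        truth.chrom, center - half, center + half,
                        name=f"{assay}_{rep}_{trow.tss_id}",
                    ))
                elif trow.open_status == "Closed200":
                    center = trow.pos + sign * config.band_peak_offset + jitter
                    half = config.band_peak_width // 2
                    peaks.append(GenomicInterval(
                        truth.chrom, center - half, center + half,
                        name=f"{assay}_{rep}_{trow.tss_id}",
                    ))
                # Closed2000: no peak at all
            reps.append(peaks)
        assays[assay] = reps
    return assays


def generate_chip_sites(truth: SyntheticTruth,
                        config: SyntheticConfig | None = None):
    """ChIP-seq-like binding-site intervals: TSS-proximal mixture + background.

    Site midpoints come from a mixture of a promoter-proximal Gaussian
    (centered ``chip_offset_mean`` bp upstream of a random TSS, strand-
    oriented) and a uniform genomic background.  Returns
    ``(sites, background_density_per_bp)``.
    """
    config = config or truth.config
    rng = _rng(config, 3)
    n = config.chip_n_sites
    w = config.chip_site_width
    glen = config.genome_length
    tss_pos = truth.tss["pos"].to_numpy()
    tss_sign = np.where(truth.tss["strand"].to_numpy() == "+", 1, -1)
    is_prox = rng.random(n) < config.chip_promoter_weight
    mids = np.empty(n)
    n_prox = int(is_prox.sum())
    if n_prox and len(tss_pos):
        pick = rng.integers(0, len(tss_pos), size=n_prox)
        offs = rng.normal(config.chip_offset_mean, config.chip_offset_sd,
                          size=n_prox)
        mids[is_prox] = tss_pos[pick] + tss_sign[pick] * offs
    mids[~is_prox] = rng.uniform(0, glen, size=n - n_prox)
    mids = np.clip(np.round(mids), w, glen - w).astype(int)
    sites = [
        GenomicInterval(truth.chrom, int(m - w // 2), int(m - w // 2 + w),
                        name=f"site_{i}")
        for i, m in enumerate(sorted(mids))
    ]
    bg_density = n * (1 - config.chip_promoter_weight) / glen
    return sites, bg_density


def generate_study(config: SyntheticConfig, with_sequence: bool = True):
    """Convenience wrapper: run every generator stage.

    Returns a dict with genome, gene_models, truth, tag_table, design,
    open_chromatin, chip_sites, chip_background_density.
    """
    genome, gene_models, truth = generate_genome(config, with_sequence)
    tag_table, design = generate_cage_counts(truth, config)
    chromatin = generate_open_chromatin(truth, config)
    chip_sites, bg = generate_chip_sites(truth, config)
    return dict(
        genome=genome, gene_models=gene_models, truth=truth,
        tag_table=tag_table, design=design, open_chromatin=chromatin,
        chip_sites=chip_sites, chip_background_density=bg,
    )
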