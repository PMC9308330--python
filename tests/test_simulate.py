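import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cageprom.io import write_fasta
from cageprom.simulate import (
    SyntheticConfig, default_pwms, generate_cage_counts, generate_chip_sites,
    generate_genome, generate_open_chromatin,
)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(de_fraction=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(n_subjects=1)
        with pytest.raises(ValueError):
            SyntheticConfig(time_points=("pre",))

    def test_yaml_round_trip(self, tmp_path):
        cfg = SyntheticConfig(seed=5, n_genes=33, de_fraction=0.2)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SyntheticConfig.from_yaml(p) == cfg


class TestGenerateGenome:
    def test_same_seed_byte_identical_fasta(self, tmp_path):
        cfg = SyntheticConfig(seed=9, n_genes=20)
        g1, _, _ = generate_genome(cfg)
        g2, _, _ = generate_genome(cfg)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(g1, p1)
        write_fasta(g2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_single_tss_config(self):
        cfg = SyntheticConfig(seed=1, n_genes=30, tss_per_gene_probs=(1, 0, 0))
        _, _, truth = generate_genome(cfg, with_sequence=False)
        assert (truth.genes["k"] == 1).all()
        assert not truth.genes["dtu"].any()  # DTU needs >= 2 TSSs

    def test_plant_rate_one_writes_consensus_everywhere(self):
        cfg = SyntheticConfig(seed=2, n_genes=60, de_fraction=0.5,
                              motif_plant_rate=1.0)
        genome, _, truth = generate_genome(cfg)
        seq = genome[cfg.chrom]
        target = next(p for p in default_pwms()
                      if p.matrix_id == cfg.planted_motif)
        cons = target.consensus
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(cons))
        de_genes = set(truth.genes.loc[truth.genes["de"], "gene_id"])
        assert de_genes
        assert set(truth.motifs["gene_id"]) == de_genes
        for row in truth.genes[truth.genes["de"]].itertuples():
            c = row.canonical_pos
            window = seq[c - 450: c + 450]
            assert cons in window or rc in window

    def test_tss_invariants(self):
        cfg = SyntheticConfig(seed=3, n_genes=40)
        _, models, truth = generate_genome(cfg, with_sequence=False)
        # proportions sum to 1 per gene
        sums = truth.tss.groupby("gene_id")["baseline_prop"].sum()
        assert np.allclose(sums, 1.0)
        # model TSS equals 5'-most exon boundary in strand orientation
        for m in models:
            for tx in m.transcripts:
                if m.strand == "+":
                    assert tx.tss == tx.exons[0][0]
                else:
                    assert tx.tss == tx.exons[-1][1] - 1

    def test_alt_codon_genes_have_distinct_codons(self):
        cfg = SyntheticConfig(seed=4, n_genes=60, alt_codon_fraction=1.0)
        _, models, truth = generate_genome(cfg, with_sequence=False)
        by_id = {m.gene_id: m for m in models}
        for row in truth.genes.itertuples():
            codons = {tx.start_codon for tx in by_id[row.gene_id].transcripts
                      if tx.start_codon is not None}
            if row.alt_codon:
                assert len(codons) >= 2
            elif row.coding:
                assert len(codons) == 1


class TestGenerateCounts:
    def test_determinism(self):
        cfg = SyntheticConfig(seed=11, n_genes=15)
        _, _, truth = generate_genome(cfg, with_sequence=False)
        t1, d1 = generate_cage_counts(truth)
        t2, d2 = generate_cage_counts(truth)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_poisson_limit_moments(self):
        """dispersion -> 0 and no subject effect: Fano factor near 1."""
        cfg = SyntheticConfig(seed=12, n_genes=30, nb_dispersion=0.0,
                              subject_sd=0.0, de_fraction=0, dtu_fraction=0,
                              tss_per_gene_probs=(1, 0, 0))
        _, _, truth = generate_genome(cfg, with_sequence=False)
        tags, design = generate_cage_counts(truth)
        from cageprom.clustering import cluster_tags

        _, counts = cluster_tags(tags)
        mat = counts.to_numpy(dtype=float)
        # pooled per-cluster sample mean within 3 SE of each cluster's
        # empirical mean under Poisson (SE = sqrt(mean / n))
        n = mat.shape[1]
        fano = mat.var(axis=1, ddof=1) / mat.mean(axis=1)
        # chi2-based 99% band for the Fano factor of Poisson counts
        lo = stats.chi2.ppf(0.005, n - 1) / (n - 1)
        hi = stats.chi2.ppf(0.995, n - 1) / (n - 1)
        assert ((fano > lo) & (fano < hi)).mean() > 0.9

    def test_overdispersion_visible(self):
        cfg = SyntheticConfig(seed=13, n_genes=30, nb_dispersion=0.5,
                              subject_sd=0.0, de_fraction=0, dtu_fraction=0,
                              tss_per_gene_probs=(1, 0, 0))
        _, _, truth = generate_genome(cfg, with_sequence=False)
        tags, _ = generate_cage_counts(truth)
        from cageprom.clustering import cluster_tags

        _, counts = cluster_tags(tags)
        mat = counts.to_numpy(dtype=float)
        fano = mat.var(axis=1, ddof=1) / mat.mean(axis=1)
        assert np.median(fano) > 5  # var = mu(1 + disp*mu), mu >> 1

    def test_balanced_proportions_within_binomial_ci(self):
        """50/50 two-TSS genes, no DTU: pooled split within binomial 99% CI."""
        # Poisson limit: conditional on the gene total, the two-cluster split
        # is exactly binomial(n, 0.5)
        cfg = SyntheticConfig(seed=14, n_genes=40, dtu_fraction=0.0,
                              de_fraction=0.0, tss_per_gene_probs=(0, 1, 0),
                              baseline_props={2: (0.5, 0.5)},
                              nb_dispersion=0.0, subject_sd=0.0)
        _, _, truth = generate_genome(cfg, with_sequence=False)
        tags, design = generate_cage_counts(truth)
        from cageprom.clustering import cluster_tags

        clusters, counts = cluster_tags(tags)
        ok = 0
        for gid, sub in truth.tss.groupby("gene_id"):
            pos = sub["pos"].to_numpy()
            totals = []
            for p in pos:
                m = (clusters["start"] <= p + 60) & (clusters["end"] >= p - 60) \
                    & (clusters["strand"] == sub["strand"].iloc[0])
                ids = clusters.loc[m, "cluster_id"]
                totals.append(counts.loc[ids].to_numpy().sum())
            n = sum(totals)
            lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
            ok += lo <= totals[0] <= hi
        assert ok >= 0.9 * truth.genes.shape[0]


class TestOpenChromatin:
    def test_all_open_every_tss_covered(self):
        cfg = SyntheticConfig(seed=21, n_genes=40, closed200_fraction=0,
                              closed2000_fraction=0)
        _, _, truth = generate_genome(cfg, with_sequence=False)
        assays = generate_open_chromatin(truth)
        for assay in ("atac", "dnase"):
            for rep in assays[assay]:
                for trow in truth.tss.itertuples():
                    assert any(iv.start - 200 <= trow.pos < iv.end + 200
                               for iv in rep)

    def test_closed2000_has_no_nearby_peak(self):
        cfg = SyntheticConfig(seed=22, n_genes=60, closed2000_fraction=0.3,
                              closed200_fraction=0.0)
        _, _, truth = generate_genome(cfg, with_sequence=False)
        assays = generate_open_chromatin(truth)
        closed = truth.tss[truth.tss["open_status"] == "Closed2000"]
        assert len(closed)
        peaks = [iv for assay in assays.values() for rep in assay for iv in rep]
        for trow in closed.itertuples():
            dists = [max(0, max(iv.start - trow.pos, trow.pos + 1 - iv.end))
                     for iv in peaks]
            assert min(dists, default=10**9) > 2000

    def test_mean_upstream_shift(self):
        cfg = SyntheticConfig(seed=23, n_genes=200, peak_shift=-300,
                              peak_jitter=50, closed200_fraction=0,
                              closed2000_fraction=0,
                              tss_per_gene_probs=(1, 0, 0))
        _, _, truth = generate_genome(cfg, with_sequence=False)
        assays = generate_open_chromatin(truth)
        sign = {"+": 1, "-": -1}
        offs = []
        tss = truth.tss.reset_index(drop=True)
        for iv, trow in zip(assays["atac"][0], tss.itertuples()):
            mid = (iv.start + iv.end) / 2
            offs.append((mid - trow.pos) * sign[trow.strand])
        assert abs(np.mean(offs) - (-300)) < 100

    def test_determinism(self):
        cfg = SyntheticConfig(seed=24, n_genes=10)
        _, _, truth = generate_genome(cfg, with_sequence=False)
        a1 = generate_open_chromatin(truth)
        a2 = generate_open_chromatin(truth)
        assert [(iv.start, iv.end) for iv in a1["atac"][0]] == [
            (iv.start, iv.end) for iv in a2["atac"][0]
        ]


class TestChipSites:
    def test_background_only_poisson_windows(self):
        cfg = SyntheticConfig(seed=31, n_genes=50, chip_promoter_weight=0.0,
                              chip_n_sites=4000)
        _, _, truth = generate_genome(cfg, with_sequence=False)
        sites, bg_density = generate_chip_sites(truth)
        rate = 4000 / cfg.genome_length
        lam = rate * 4000  # +/- 2000 bp window
        lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
        ok = 0
        tss = truth.tss
        mids = np.array([(s.start + s.end) // 2 for s in sites])
        for trow in tss.itertuples():
            k = ((mids >= trow.pos - 2000) & (mids < trow.pos + 2000)).sum()
            ok += lo <= k <= hi
        assert ok >= 0.95 * len(tss)

    def test_promoter_weight_one_concentrates(self):
        cfg = SyntheticConfig(seed=32, n_genes=50, chip_promoter_weight=1.0,
                              chip_n_sites=3000)
        _, _, truth = generate_genome(cfg, with_sequence=False)
        sites, _ = generate_chip_sites(truth)
        tss_pos = np.sort(truth.tss["pos"].to_numpy())
        mids = np.array([(s.start + s.end) // 2 for s in sites])
        j = np.searchsorted(tss_pos, mids)
        j = np.clip(j, 1, len(tss_pos) - 1)
        near = np.minimum(np.abs(mids - tss_pos[j - 1]),
                          np.abs(mids - tss_pos[j]))
        assert (near <= 2000).mean() > 0.9

    def test_determinism(self):
        cfg = SyntheticConfig(seed=33, n_genes=10)
        _, _, truth = generate_genome(cfg, with_sequence=False)
        s1, _ = generate_chip_sites(truth)
        s2, _ = generate_chip_sites(truth)
        assert [(s.start, s.end) for s in s1] == [(s.start, s.end) for s in s2]
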