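import numpy as np
import pandas as pd
import pytest
from scipy.stats import betabinom, multinomial

from cageprom.differential import bh_adjust, dm_loglik, dtu_lrt, fit_dm_pi, \
    size_factors
from cageprom.differential import test_de as de_test
from cageprom.differential import test_dtu as dtu_test


def sample_dm(rng, n_samples, totals, pi, gamma):
    """Draw Dirichlet-multinomial count vectors."""
    alpha = gamma * np.asarray(pi)
    out = np.empty((n_samples, len(pi)), dtype=int)
    for i in range(n_samples):
        p = rng.dirichlet(alpha)
        out[i] = rng.multinomial(totals, p)
    return out


class TestSizeFactors:
    def test_hand_median_of_ratios(self):
        counts = pd.DataFrame({"a": [2, 2], "b": [8, 8]})
        f = size_factors(counts)
        assert np.allclose(f.to_numpy(), [0.5, 2.0])

    def test_identity(self):
        counts = pd.DataFrame({"a": [3, 10, 7], "b": [3, 10, 7]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 100, size=(50, 3)),
                              columns=list("abc"))
        f1 = size_factors(counts)
        counts2 = counts.copy()
        counts2["b"] *= 3
        f2 = size_factors(counts2)
        # scaling sample b by 3 multiplies its factor by 3 relative to the rest
        assert np.allclose(f2["b"] / f2["a"], 3 * f1["b"] / f1["a"])
        assert np.allclose(f2["c"] / f2["a"], f1["c"] / f1["a"])

    def test_no_positive_gene_errors(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)


class TestBH:
    @pytest.mark.parametrize("pvec", [
        [0.01, 0.02, 0.03, 0.04, 0.05],
        [0.5, 0.001, 0.2, 0.04, 0.9],
        [0.04, 0.04, 0.04],
        [1.0, 1.0],
        [0.0005],
    ])
    def test_matches_textbook_step_up(self, pvec):
        p = np.asarray(pvec, dtype=float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running_min = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            running_min = min(running_min, p[i] * m / (rank_from_top + 1))
            adj[i] = running_min
        assert np.allclose(bh_adjust(p), adj)
        # adjusted values monotone nondecreasing in sorted-p order
        assert np.all(np.diff(bh_adjust(p)[order]) >= -1e-12)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestDE:
    def counts_and_design(self, n_units=20, n_subjects=6, seed=0, fc_at=None):
        rng = np.random.default_rng(seed)
        rows, cols = {}, []
        design = {}
        for i in range(n_subjects):
            for t in ("pre", "1h"):
                design[f"S{i}_{t}"] = dict(subject=f"S{i}", time=t)
        design = pd.DataFrame.from_dict(design, orient="index")
        base = rng.integers(50, 500, size=(n_units, 1))
        data = {}
        for s in design.index:
            mult = 1.0
            if fc_at is not None and design.loc[s, "time"] == "1h":
                mult = fc_at
            data[s] = (base[:, 0] * mult).astype(int)
        return pd.DataFrame(data), design

    def test_null_identity(self):
        counts, design = self.counts_and_design()
        res = de_test(counts, design)
        assert np.allclose(res["fold_change"], 1.0)
        assert not res["deg"].any()

    def test_fold_change_exactly_at_threshold_not_deg(self):
        # a few units get an exact 1.25x shift at 1h (majority stays null so
        # size factors are 1); zero across-subject variance makes p tiny, yet
        # FC == 1.25 must fail the strict |FC| > 1.25 rule
        counts, design = self.counts_and_design()
        t_cols = [s for s in design.index if design.loc[s, "time"] == "1h"]
        b_cols = [s for s in design.index if design.loc[s, "time"] == "pre"]
        shifted = counts.index[:3]
        # (norm count + 1) ratio exactly 1.25: 399+1 -> 499+1
        counts.loc[shifted, b_cols] = 399
        counts.loc[shifted, t_cols] = 499
        res = de_test(counts, design)
        strict = res[res["unit_id"].isin(shifted)
                     & np.isclose(res["fold_change"], 1.25, atol=1e-9)]
        assert len(strict) > 0
        assert (strict["p"] < 1e-100).all()
        assert not strict["deg"].any()

    def test_rescaling_one_sample_invariant(self):
        counts, design = self.counts_and_design(seed=3)
        res1 = de_test(counts, design)
        counts2 = counts.copy()
        counts2[counts2.columns[0]] *= 7
        res2 = de_test(counts2, design)
        assert np.allclose(res1["log2fc"], res2["log2fc"], atol=1e-9)

    def test_all_zero_unit_untested(self):
        counts, design = self.counts_and_design()
        counts.iloc[0] = 0
        res = de_test(counts, design)
        assert not res.iloc[0]["tested"]
        assert np.isnan(res.iloc[0]["p"])

    def test_too_few_pairs_errors(self):
        counts, design = self.counts_and_design(n_subjects=2)
        with pytest.raises(ValueError, match="3"):
            de_test(counts, design)

    def test_type_one_error_calibrated(self):
        """Null NB counts with paired subject effects: raw p at 5% nominal."""
        from cageprom.simulate import SyntheticConfig, generate_cage_counts, \
            generate_genome
        from cageprom.clustering import cluster_tags
        from cageprom.annotation import annotate_clusters

        cfg = SyntheticConfig(seed=42, n_genes=800, de_fraction=0.0,
                              dtu_fraction=0.0, tss_per_gene_probs=(1, 0, 0),
                              time_points=("pre", "1h"))
        _, models, truth = generate_genome(cfg, with_sequence=False)
        tags, design = generate_cage_counts(truth, cfg)
        clusters, counts = cluster_tags(tags)
        annot = annotate_clusters(clusters, models)
        gene_counts = (
            counts.join(annot.set_index("cluster_id")["gene_id"])
            .dropna(subset=["gene_id"]).groupby("gene_id").sum()
        )
        res = de_test(gene_counts, design)
        frac = (res.loc[res["tested"], "p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestDMLoglik:
    def test_uniform_beta_binomial_case(self):
        # x=(1,1), pi=(.5,.5), gamma=2 -> Beta-binomial(1,1) uniform on {0,1,2}
        ll = dm_loglik([1, 1], [0.5, 0.5], 2.0)
        assert np.isclose(np.exp(ll), 1 / 3, atol=1e-12)

    def test_matches_beta_binomial_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(1, 200))
            x1 = int(rng.integers(0, n + 1))
            p1 = float(rng.uniform(0.05, 0.95))
            gamma = float(rng.uniform(0.1, 100))
            ll = dm_loglik([x1, n - x1], [p1, 1 - p1], gamma)
            ref = betabinom.logpmf(x1, n, gamma * p1, gamma * (1 - p1))
            assert np.isclose(ll, ref, atol=1e-10)

    def test_multinomial_limit(self):
        x = [5, 7, 3]
        pi = [0.3, 0.5, 0.2]
        ll = dm_loglik(x, pi, 1e8)
        ref = multinomial.logpmf(x, n=sum(x), p=pi)
        assert abs(ll - ref) < 1e-4

    def test_zero_pi_with_positive_count(self):
        assert dm_loglik([1, 1], [1.0, 0.0], 5.0) == -np.inf

    def test_gamma_domain(self):
        with pytest.raises(ValueError):
            dm_loglik([1, 1], [0.5, 0.5], 0.0)


class TestDMFit:
    def test_pi_recovery_bias(self):
        """MLE of pi over 50 datasets x 20 vectors of n=500: bias < 0.02."""
        rng = np.random.default_rng(5)
        pi_true = np.array([0.55, 0.30, 0.15])
        gamma = 30.0
        est = []
        for _ in range(50):
            X = sample_dm(rng, 20, 500, pi_true, gamma)
            est.append(fit_dm_pi(X, gamma))
        bias = np.abs(np.mean(est, axis=0) - pi_true).max()
        assert bias < 0.02

    def test_lrt_invariant_to_cluster_permutation(self):
        rng = np.random.default_rng(2)
        Xb = sample_dm(rng, 8, 150, [0.6, 0.3, 0.1], 25.0)
        Xt = sample_dm(rng, 8, 150, [0.2, 0.5, 0.3], 25.0)
        r1 = dtu_lrt(Xb, Xt)
        perm = [2, 0, 1]
        r2 = dtu_lrt(Xb[:, perm], Xt[:, perm])
        assert np.isclose(r1["lrt"], r2["lrt"], atol=1e-6)

    def test_null_identity(self):
        X = np.array([[30, 70]] * 10)
        r = dtu_lrt(X, X.copy())
        assert r["lrt"] <= 1e-6
        assert r["p"] > 0.99


class TestDTU:
    def design(self, n=10):
        rows = {}
        for i in range(n):
            for t in ("pre", "1h"):
                rows[f"S{i}_{t}"] = dict(subject=f"S{i}", time=t)
        return pd.DataFrame.from_dict(rows, orient="index")

    def tables(self, Xb, Xt, gene="g"):
        design = self.design(len(Xb))
        cols_b = [s for s in design.index if s.endswith("pre")]
        cols_t = [s for s in design.index if s.endswith("1h")]
        K = Xb.shape[1]
        counts = pd.DataFrame(
            np.hstack([Xb.T, Xt.T]), columns=cols_b + cols_t,
            index=[f"{gene}_c{k}" for k in range(K)],
        )
        annot = pd.DataFrame(dict(cluster_id=counts.index, gene_id=gene))
        return counts, annot, design

    def test_single_cluster_gene_untested(self):
        rng = np.random.default_rng(0)
        counts, annot, design = self.tables(
            rng.integers(10, 50, (10, 1)), rng.integers(10, 50, (10, 1))
        )
        res = dtu_test(counts, annot, design)
        assert not res.iloc[0]["tested"]

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        Xb = sample_dm(rng, 10, 200, [0.8, 0.2], 30.0)
        Xt = sample_dm(rng, 10, 200, [0.2, 0.8], 30.0)
        counts, annot, design = self.tables(Xb, Xt)
        res = dtu_test(counts, annot, design)
        assert res.iloc[0]["dtu"]
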