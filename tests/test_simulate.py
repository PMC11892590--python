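"""The synthetic-data generator: trees, rate scalars, Brownian traits, counts."""

import numpy as np
import pytest

import phyloprev as pp
from phyloprev.trees import phylo_covariance


class TestSimulateTree:
    def test_ultrametric_and_reproducible(self):
        t1 = pp.simulate_tree(50, birth_rate=1.0, seed=3)
        taxa = sorted(l.taxon.label for l in t1.leaf_node_iter())
        assert len(taxa) == 50
        depths = np.diag(phylo_covariance(t1, taxa).matrix)
        assert np.allclose(depths, depths[0], atol=1e-9)
        t2 = pp.simulate_tree(50, birth_rate=1.0, seed=3)
        assert (pp.write_trees(pp.TreePosterior([t1]))
                == pp.write_trees(pp.TreePosterior([t2])))

    def test_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            pp.simulate_tree(1)

    def test_yule_heights_shrink_with_birth_rate(self):
        """Yule expected tree height scales as 1/b: over seeded replicates the
        mean height at b=2 is about half the mean height at b=1."""
        h1 = []
        h2 = []
        for s in range(60):
            for b, acc in ((1.0, h1), (2.0, h2)):
                t = pp.simulate_tree(20, birth_rate=b, seed=1000 + s)
                leaf = next(t.leaf_node_iter())
                d, node = 0.0, leaf
                while node.parent_node is not None:
                    d += node.edge.length or 0.0
                    node = node.parent_node
                acc.append(d)
        ratio = np.mean(h1) / np.mean(h2)
        assert 1.6 < ratio < 2.5


class TestRateScaledTrees:
    def test_sparse_with_zero_fraction_is_identity(self):
        t = pp.simulate_tree(20, seed=1)
        scaled = pp.simulate_rate_scaled_tree(t, "sparse", {"fraction": 0.0},
                                              seed=2)
        taxa = sorted(l.taxon.label for l in t.leaf_node_iter())
        assert np.allclose(phylo_covariance(t, taxa).matrix,
                           phylo_covariance(scaled, taxa).matrix)

    def test_lognormal_scalar_moments(self):
        """tau = 0.5: empirical mean of log scalars ~ 0 and SD ~ 0.5."""
        t = pp.simulate_tree(501, seed=4)  # ~1000 branches
        scaled = pp.simulate_rate_scaled_tree(t, "lognormal", {"tau": 0.5},
                                              seed=5)
        logs = []
        for e0, e1 in zip(t.preorder_edge_iter(), scaled.preorder_edge_iter()):
            if e0.length is not None and e0.length > 0:
                logs.append(np.log(e1.length / e0.length))
        logs = np.array(logs)
        se = 0.5 / np.sqrt(len(logs))
        assert abs(logs.mean()) < 3 * se
        assert abs(logs.std() - 0.5) < 3 * se

    def test_invalid_params_rejected(self):
        t = pp.simulate_tree(5, seed=1)
        with pytest.raises(ValueError):
            pp.simulate_rate_scaled_tree(t, "lognormal", {"tau": -1})
        with pytest.raises(ValueError):
            pp.simulate_rate_scaled_tree(t, "sparse", {"shape": -2})
        with pytest.raises(ValueError):
            pp.simulate_rate_scaled_tree(t, "nope")


class TestBrownianMotion:
    def test_degenerate_rate_pins_tips_to_root(self):
        t = pp.simulate_tree(20, seed=6)
        vals = pp.simulate_body_size(t, pp.BrownianProcess(1e-12, 3.0), seed=7)
        assert np.allclose(list(vals.values()), 3.0, atol=1e-4)

    def test_two_tip_contrast_variance(self):
        tree = pp.read_trees("(A:1,B:1);")[0]
        bm = pp.BrownianProcess(sigma2=0.5, root_value=0.0)
        diffs = [d["A"] - d["B"] for d in
                 (pp.simulate_body_size(tree, bm, seed=s) for s in range(2000))]
        var = np.var(diffs)
        se = 1.0 * np.sqrt(2 / 2000)  # var of sample variance ~ 2 sigma^4 / n
        assert abs(var - 1.0) < 3 * se

    def test_tip_covariance_matches_sigma2_A(self):
        tree = pp.read_trees("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")[0]
        taxa = ["A", "B", "C", "D"]
        A = phylo_covariance(tree, taxa).matrix
        bm = pp.BrownianProcess(sigma2=0.8, root_value=0.0)
        sims = np.array([[pp.simulate_body_size(tree, bm, seed=s)[t]
                          for t in taxa] for s in range(2000)])
        emp = np.cov(sims.T)
        se = 0.8 * 2 * np.sqrt(2 / 2000)
        assert np.allclose(emp, 0.8 * A, atol=3 * se + 0.05)


class TestSimulateCounts:
    def test_iid_poisson_limit(self):
        """G = R = 0 and only an intercept ln 5: counts are iid Poisson(5)."""
        n = 1000
        tree = pp.read_trees("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")[0]
        cfg = pp.SyntheticConfig(
            n_tips_per_class=n, classes=("bird",), intercept=np.log(5.0),
            necropsy_slope=0.0, body_size_slope=0.0, pathwise_slope=None,
            G=np.zeros((2, 2)), R=np.zeros((2, 2)),
            necropsy_log_mean=6.0, necropsy_log_sd=0.1,
            cap_at_necropsies=False, seed=8)
        body = {f"s{i}": 5.0 for i in range(n)}
        sim = pp.simulate_counts(cfg, tree, body)
        y = np.array([[r.n_neoplasia, r.n_malignancy] for r in sim.records])
        se = np.sqrt(5.0 / n)
        assert abs(y[:, 0].mean() - 5.0) < 3 * se
        assert abs(y[:, 1].mean() - 5.0) < 3 * se

    def test_necropsy_slope_one_acts_as_offset(self):
        """With unit necropsy slope and no other effects, expected counts are
        proportional to effort: the regression of log(y/N) on log N is flat."""
        n = 1500
        tree = pp.read_trees("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")[0]
        cfg = pp.SyntheticConfig(
            n_tips_per_class=n, classes=("bird",), intercept=-2.0,
            necropsy_slope=1.0, body_size_slope=0.0, pathwise_slope=None,
            G=np.zeros((2, 2)), R=np.zeros((2, 2)),
            necropsy_log_mean=4.0, necropsy_log_sd=1.0,
            cap_at_necropsies=False, seed=9)
        body = {f"s{i}": 5.0 for i in range(n)}
        sim = pp.simulate_counts(cfg, tree, body)
        N = np.array([r.n_necropsies for r in sim.records])
        y = np.array([r.n_neoplasia for r in sim.records])
        keep = y > 0
        slope = np.polyfit(np.log(N[keep]), np.log(y[keep] / N[keep]), 1)[0]
        assert abs(slope) < 0.05

    def test_hierarchical_mode_enforces_nesting(self):
        cfg = pp.SyntheticConfig(n_tips_per_class=50, hierarchical=True, seed=10)
        sim = pp.simulate_dataset(cfg)
        for r in sim.records:
            assert r.n_malignancy <= r.n_neoplasia

    def test_records_satisfy_invariants(self, small_sim):
        for r in small_sim.records:
            r.validate()

    def test_truth_is_stored_for_recovery(self, small_sim):
        truth = small_sim.truth
        assert truth["body_size_slope"] == (0.15, 0.15)
        assert truth["pathwise_slope"] == (-0.8, -0.8)
        assert truth["a"].shape == (60, 2)
        assert np.all(np.linalg.eigvalsh(truth["G"]) >= 0)


class TestEndToEndSignal:
    def test_pathwise_rates_positive_and_aligned(self, small_sim):
        pw = small_sim.pathwise
        assert (pw.summary > 0).all()
        assert set(pw.summary.index) == {r.species for r in small_sim.records}

    def test_rate_heterogeneity_creates_pathwise_spread(self, small_sim):
        logpw = np.log(small_sim.pathwise.summary.values)
        assert logpw.std() > 0.1

    def test_pathwise_rate_tracks_body_size_evolution(self):
        """Fast lineages accumulate both pathwise rate and body-size change:
        log pathwise rate correlates positively with |log body size - root|
        across tips (aggregated over seeds)."""
        from scipy.stats import spearmanr

        rhos = []
        for s in (1, 2, 3):
            sim = pp.simulate_dataset(pp.SyntheticConfig(n_tips_per_class=50,
                                                         seed=s))
            ds = sim.dataset()
            dev = np.abs(ds.table.log_body_size
                         - sim.config.brownian.root_value)
            rhos.append(spearmanr(ds.table.log_pathwise, dev).statistic)
        assert np.mean(rhos) > 0.2
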