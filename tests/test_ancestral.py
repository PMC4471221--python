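import math

import numpy as np
import pytest
from scipy import linalg, stats

from cochlevol import ancestral as anc
from cochlevol import treeio
from cochlevol.errors import DegenerateDataError, InvalidParameterError
from cochlevol.synthetic import simulate_bm_tips, simulate_tree

from conftest import tip_vector

FIVE_TAXON = "(((A:0.4,B:0.6):0.5,(C:0.5,D:0.3):0.7):0.3,E:1.4);"


class TestAnalytic:
    def test_star_root_is_arithmetic_mean(self):
        tree = treeio.read_newick("(A:1,B:1,C:1,D:1);")
        y = np.array([1.0, 3.0, 5.0, 7.0])
        res = anc.analytic_ancestral(y, tree, sigma2=1.0, lam=1.0,
                                     tip_order=("A", "B", "C", "D"))
        mean, sd = res["A|B|C|D"]
        assert mean == pytest.approx(4.0, abs=1e-10)

    def test_root_equals_gls_weighted_mean(self):
        tree = treeio.read_newick(FIVE_TAXON)
        V = treeio.vcv_from_tree(tree)
        rng = np.random.default_rng(1)
        y = rng.standard_normal(5)
        res = anc.analytic_ancestral(y, tree, sigma2=1.3, lam=1.0,
                                     tip_order=V.tip_order)
        ones = np.ones(5)
        Vi = np.linalg.inv(V.matrix)
        gls = float(ones @ Vi @ y) / float(ones @ Vi @ ones)
        root_id = "|".join(sorted(V.tip_order))
        assert res[root_id][0] == pytest.approx(gls, abs=1e-10)

    def test_zero_branch_node_pins_to_tip(self):
        tree = treeio.read_newick("((A:0.000001,B:1):1,C:2);")
        y = np.array([2.5, -1.0, 4.0])
        res = anc.analytic_ancestral(y, tree, sigma2=1.0, lam=1.0,
                                     node_id="A|B", alpha=0.0,
                                     tip_order=("A", "B", "C"))
        mean, sd = res["A|B"]
        assert mean == pytest.approx(2.5, abs=1e-3)
        assert sd < 1e-2

    def test_joint_mvn_conditional_oracle(self):
        # independent oracle: assemble the full joint (tips + node)
        # covariance explicitly and apply the textbook Gaussian
        # conditioning formulas
        tree = treeio.read_newick(FIVE_TAXON)
        V = treeio.vcv_from_tree(tree)
        lam, sigma2, alpha = 0.8, 1.7, 0.4
        rng = np.random.default_rng(2)
        y = rng.standard_normal(5)
        res = anc.analytic_ancestral(y, tree, sigma2=sigma2, lam=lam,
                                     alpha=alpha, tip_order=V.tip_order)
        depths = treeio.node_depths(tree)
        idx = {t: i for i, t in enumerate(V.tip_order)}
        for node in tree.preorder_internal_node_iter():
            nid = "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))
            d_m = depths[node]
            shared = np.zeros(5)
            for leaf in tree.leaf_node_iter():
                i = idx[leaf.taxon.label]
                anc_set = []
                p = node
                while p is not None:
                    anc_set.append(p)
                    p = p.parent_node
                q = leaf
                while q not in anc_set:
                    q = q.parent_node
                shared[i] = depths[q] if q is not node else d_m
            Vt = treeio.lambda_transform(V, lam).matrix * sigma2
            c_mt = lam * shared * sigma2
            v_m = lam * d_m * sigma2
            mean = alpha + c_mt @ np.linalg.inv(Vt) @ (y - alpha)
            var = v_m - c_mt @ np.linalg.inv(Vt) @ c_mt
            assert res[nid][0] == pytest.approx(mean, abs=1e-9)
            assert res[nid][1] == pytest.approx(math.sqrt(max(var, 0)), abs=1e-9)


class TestMcmc:
    def test_two_tip_symmetry(self):
        tree = treeio.read_newick("(A:1,B:1);")
        cfg = anc.ChainConfig(iterations=21000, burn_in=1000, thinning=4,
                              seed=3)
        post = anc.mcmc_ancestral(np.array([0.0, 2.0]), tree, cfg,
                                  tip_order=("A", "B"))
        root = post["A|B"]
        assert root.mean == pytest.approx(1.0, abs=4 * root.sd / math.sqrt(500))

    def test_fixed_params_match_analytic(self):
        tree = treeio.read_newick(FIVE_TAXON)
        V = treeio.vcv_from_tree(tree)
        rng = np.random.default_rng(4)
        y = rng.standard_normal(5)
        alpha, sigma2, lam = 0.3, 1.2, 0.7
        cfg = anc.ChainConfig(iterations=110_000, burn_in=10_000, thinning=10,
                              seed=5, fixed_alpha=alpha, fixed_sigma2=sigma2,
                              fixed_lambda=lam)
        post = anc.mcmc_ancestral(y, tree, cfg, tip_order=V.tip_order)
        exact = anc.analytic_ancestral(y, tree, sigma2=sigma2, lam=lam,
                                       alpha=alpha, tip_order=V.tip_order)
        for nid, (mean, sd) in exact.items():
            assert post[nid].mean == pytest.approx(mean, abs=0.05 * sd)
            assert post[nid].sd == pytest.approx(sd, rel=0.1)

    def test_seed_reproducibility(self):
        tree = treeio.read_newick(FIVE_TAXON)
        y = np.array([0.1, 0.5, -0.3, 0.9, 1.4])
        cfg = anc.ChainConfig(iterations=5000, burn_in=500, thinning=5, seed=6)
        p1 = anc.mcmc_ancestral(y, tree, cfg)
        p2 = anc.mcmc_ancestral(y, tree, cfg)
        for nid in p1:
            assert np.array_equal(p1[nid].samples, p2[nid].samples)

    def test_constant_trait_rejected(self):
        tree = treeio.read_newick(FIVE_TAXON)
        cfg = anc.ChainConfig(iterations=1000, burn_in=100, thinning=2, seed=7)
        with pytest.raises(DegenerateDataError):
            anc.mcmc_ancestral(np.full(5, 2.0), tree, cfg)

    def test_convergence_with_chain_length(self):
        # Monte-Carlo error of the node mean should shrink roughly with
        # sqrt(sample count)
        tree = treeio.read_newick(FIVE_TAXON)
        V = treeio.vcv_from_tree(tree)
        rng = np.random.default_rng(8)
        y = rng.standard_normal(5)
        exact = anc.analytic_ancestral(y, tree, sigma2=1.0, lam=1.0,
                                       alpha=0.0, tip_order=V.tip_order)
        errs = []
        for iters in (2000, 32000):
            cfg = anc.ChainConfig(iterations=iters, burn_in=0, thinning=1,
                                  seed=9, fixed_alpha=0.0, fixed_sigma2=1.0,
                                  fixed_lambda=1.0)
            post = anc.mcmc_ancestral(y, tree, cfg, tip_order=V.tip_order)
            errs.append(np.mean([abs(post[nid].mean - exact[nid][0])
                                 for nid in exact]))
        assert errs[1] < errs[0]

    def test_posterior_shrinks_with_short_branches(self):
        near = treeio.read_newick("((A:0.01,B:0.01):1.0,(C:1,D:1):0.01);")
        far = treeio.read_newick("((A:1.0,B:1.0):0.01,(C:1,D:1):0.01);")
        y = np.array([1.0, 1.2, -0.5, -0.2])
        kw = dict(sigma2=1.0, lam=1.0, alpha=0.0)
        sd_near = anc.analytic_ancestral(y, near, node_id="A|B",
                                         tip_order=("A", "B", "C", "D"), **kw)["A|B"][1]
        sd_far = anc.analytic_ancestral(y, far, node_id="A|B",
                                        tip_order=("A", "B", "C", "D"), **kw)["A|B"][1]
        assert sd_near < sd_far


class TestZscore:
    def make_posterior(self, mean=2.0, sd=0.5, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        return anc.AncestralPosterior(
            "A|B", mean + sd * rng.standard_normal(n),
            anc.ChainConfig(iterations=n, burn_in=0, thinning=1, seed=seed))

    def test_fossil_at_mean(self):
        post = self.make_posterior(seed=1)
        dev = anc.zscore_fossil(post.mean, post, tail="right")
        assert dev.z == pytest.approx(0.0, abs=1e-9)
        assert dev.p == pytest.approx(0.5, abs=1e-9)

    def test_two_sd_right_tail(self):
        post = self.make_posterior(seed=2)
        dev = anc.zscore_fossil(post.mean + 2 * post.sd, post, tail="right")
        assert dev.z == pytest.approx(2.0, abs=1e-9)
        assert dev.p == pytest.approx(0.02275, abs=1e-4)
        assert dev.significant

    def test_auto_tail_side(self):
        post = self.make_posterior(seed=3)
        low = anc.zscore_fossil(post.mean - post.sd, post, tail="auto")
        high = anc.zscore_fossil(post.mean + post.sd, post, tail="auto")
        assert low.tail == "left" and high.tail == "right"

    def test_calibration_uniform_p(self):
        # fossils drawn from the posterior itself give uniform one-tailed p
        post = self.make_posterior(mean=1.0, sd=0.7, n=20000, seed=4)
        rng = np.random.default_rng(5)
        draws = post.mean + post.sd * rng.standard_normal(500)
        ps = [anc.zscore_fossil(v, post, tail="right").p for v in draws]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_posterior_rejected(self):
        post = anc.AncestralPosterior(
            "A|B", np.full(100, 1.0),
            anc.ChainConfig(iterations=100, burn_in=0, thinning=1, seed=0))
        with pytest.raises(DegenerateDataError):
            anc.zscore_fossil(1.5, post)

    def test_bad_tail_rejected(self):
        post = self.make_posterior(seed=6)
        with pytest.raises(InvalidParameterError):
            anc.zscore_fossil(1.0, post, tail="both")


class TestUncertaintyVsTaxa:
    def test_sd_no_larger_on_bigger_tree(self):
        # the same data-generating process observed with more taxa cannot
        # widen the posterior at a shared node
        sub_nwk = "((A:1,B:1):1,(C:1,D:1):1);"
        big_nwk = "(((A:1,B:1):1,(C:1,D:1):1):0.5,(E:2.2,F:2.2):0.3);"
        sub = treeio.read_newick(sub_nwk)
        big = treeio.read_newick(big_nwk)
        sds_big, sds_sub = [], []
        for rep in range(20):
            vals, _ = simulate_bm_tips(big, 0.0, 1.0, 1.0, seed=500 + rep)
            y_big = np.array([vals[l] for l in treeio.tip_labels(big)])
            y_sub = np.array([vals[l] for l in treeio.tip_labels(sub)])
            r_big = anc.analytic_ancestral(
                y_big, big, sigma2=1.0, lam=1.0,
                tip_order=treeio.tip_labels(big))
            r_sub = anc.analytic_ancestral(
                y_sub, sub, sigma2=1.0, lam=1.0,
                tip_order=treeio.tip_labels(sub))
            sds_big.append(r_big["A|B"][1])
            sds_sub.append(r_sub["A|B"][1])
        assert np.mean(sds_big) <= np.mean(sds_sub) + 1e-9
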