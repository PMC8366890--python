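import numpy as np
import pytest
from scipy.integrate import quad

from hapassort.gmyc import (
    GmycError,
    TooSmallError,
    candidate_thresholds,
    event_series,
    fit_gmyc,
    fit_null,
    fit_series,
    lrt_pvalue,
    mixed_loglik,
)
from hapassort.simulate import SimConfig, simulate_genealogy
from hapassort.trees import UltrametricTree, build_tree_from_heights

THREE_LEAF = "((A:0.5,B:0.5):0.5,C:1.0);"


def two_clade_tree(gap=0.5, inner=0.004):
    merges = [
        (inner * 0.25, "a1", "a2"),
        (inner * 0.5, 0, "a3"),
        (inner, 1, "a4"),
        (inner * 0.3, "b1", "b2"),
        (inner * 0.6, 3, "b3"),
        (inner * 0.9, 4, "b4"),
        (gap, 2, 5),
    ]
    return build_tree_from_heights(
        merges, ["a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"]
    )


class TestEventSeries:
    def test_threshold_at_root_is_single_cluster_null(self):
        t = UltrametricTree.from_newick(THREE_LEAF)
        s = event_series(t, t.root_height)
        assert s.n_div_events == 0
        assert s.n_coal_events == 2
        # one cluster of 3 lineages first, then 2
        assert [list(c) for c in s.cluster_terms] == [[6.0], [2.0]]

    def test_threshold_just_below_root_of_two_clades(self):
        t = two_clade_tree()
        T = sorted(t.branching_heights())[-2]  # deepest non-root node
        s = event_series(t, T)
        assert s.n_div_events == 1  # the root only
        assert len(t.clusters_at(T)) == 2

    def test_interval_count_conservation(self):
        t = two_clade_tree()
        for T in candidate_thresholds(t):
            s = event_series(t, T)
            total = t.n_leaves
            for i in range(len(s.durations)):
                in_clusters = sum(
                    (1 + np.sqrt(1 + 4 * c)) / 2 for c in s.cluster_terms[i]
                )
                # cluster_terms only lists clusters with >= 2 lineages;
                # remaining lineages are singletons or diversification lineages
                assert s.div_counts[i] + in_clusters <= total + 1e-9
                if s.event_kind[i] != 0:
                    total -= 1

    def test_preconditions(self):
        t = UltrametricTree.from_newick(THREE_LEAF)
        with pytest.raises(GmycError):
            event_series(t, 0.0)
        with pytest.raises(GmycError):
            event_series(t, 2 * t.root_height)
        tiny = UltrametricTree.from_newick("(A:1,B:1);")
        with pytest.raises(TooSmallError):
            event_series(tiny, 1.0)


class TestLikelihood:
    def test_closed_form_null_rate_mle(self):
        # 3-leaf tree, node heights 0.5 and 1.0, p fixed at 1:
        # lambda_hat = E / sum n(n-1) x = 2 / (6*0.5 + 2*0.5) = 0.5
        t = UltrametricTree.from_newick(THREE_LEAF)
        lam, p, ll = fit_null(t, fix_p=1.0)
        assert lam == pytest.approx(0.5, abs=1e-9)
        s = event_series(t, t.root_height)
        # likelihood at the MLE matches a direct evaluation
        assert ll == pytest.approx(mixed_loglik(s, 1.0, 1.0, lam, 1.0), abs=1e-9)
        # numeric optimizer can only improve on the fixed-exponent fit
        _, _, ll_free = fit_null(t)
        assert ll_free >= ll - 1e-9

    def test_rate_mle_is_stationary_point(self):
        t = UltrametricTree.from_newick(THREE_LEAF)
        lam, _, ll = fit_null(t, fix_p=1.0)
        s = event_series(t, t.root_height)
        for eps in (0.9, 1.1):
            assert mixed_loglik(s, 1.0, 1.0, lam * eps, 1.0) < ll

    def test_scale_equivariance(self):
        # loglik(c*t, lambda/c) = loglik(t, lambda) - E*log(c)
        t = two_clade_tree()
        c = 3.7
        scaled = UltrametricTree.from_newick(_scale_newick(t, c))
        # thresholds from each tree's own node heights (the candidate set),
        # so classification is identical on both sides
        s1 = event_series(t, sorted(t.branching_heights())[-2])
        s2 = event_series(scaled, sorted(scaled.branching_heights())[-2])
        lam1, p1, lam2, p2 = 2.0, 0.7, 31.0, 1.3
        ll1 = mixed_loglik(s1, lam1, p1, lam2, p2)
        ll2 = mixed_loglik(s2, lam1 / c, p1, lam2 / c, p2)
        E = s1.n_div_events + s1.n_coal_events
        assert ll2 == pytest.approx(ll1 - E * np.log(c), abs=1e-9)

    def test_zero_duration_interval_contributes_only_rate_factor(self):
        # two simultaneous cherries: one interval has zero duration
        merges = [(0.1, "a", "b"), (0.1, "c", "d"), (1.0, 0, 1)]
        t = build_tree_from_heights(merges, ["a", "b", "c", "d"])
        s = event_series(t, t.root_height)
        assert np.count_nonzero(s.durations == 0.0) == 1
        ll = mixed_loglik(s, 1.0, 1.0, 2.0, 1.0)
        assert np.isfinite(ll)

    def test_rates_must_be_positive(self):
        t = UltrametricTree.from_newick(THREE_LEAF)
        s = event_series(t, t.root_height)
        with pytest.raises(GmycError):
            mixed_loglik(s, 0.0, 1.0, 1.0, 1.0)


def _scale_newick(tree, c):
    import re

    def repl(m):
        return ":" + repr(float(m.group(1)) * c)

    return re.sub(r":([0-9.eE+-]+)", repl, tree.to_newick())


class TestFitGmyc:
    def test_profile_fit_matches_brute_force(self):
        from scipy.optimize import minimize

        t = two_clade_tree()
        T = sorted(t.branching_heights())[-2]
        s = event_series(t, T)
        prof = fit_series(s)

        def neg(v):
            return -mixed_loglik(s, np.exp(v[0]), v[1], np.exp(v[2]), v[3])

        best = min(
            (
                minimize(neg, start, method="L-BFGS-B",
                         bounds=[(-9, 9), (0, 3), (-9, 9), (0, 3)])
                for start in [(0, 1, 0, 1), (1, 0.5, 3, 1.5), (2, 2, 5, 0.5)]
            ),
            key=lambda r: r.fun,
        )
        assert prof["loglik"] == pytest.approx(-best.fun, abs=1e-6)

    def test_two_clade_tree_recovered(self):
        fit = fit_gmyc(two_clade_tree())
        assert fit.n_clusters == 2
        assert fit.p_value <= 0.05
        assert {frozenset(e) for e in fit.entities} == {
            frozenset({"a1", "a2", "a3", "a4"}),
            frozenset({"b1", "b2", "b3", "b4"}),
        }

    def test_nesting_lrt_nonnegative(self):
        cfg = SimConfig(seed=0, tau=0.01, theta=0.005)
        rng = np.random.default_rng(14)
        labels = {f"n{i}": "northern" for i in range(6)} | {
            f"s{i}": "southern" for i in range(6)
        }
        for _ in range(10):
            t = simulate_genealogy(labels, cfg, rng)
            fit = fit_gmyc(t)
            assert fit.lrt_stat >= 0.0
            assert fit.loglik >= fit.null_loglik - 1e-9

    def test_entities_partition_leaves(self):
        t = two_clade_tree()
        fit = fit_gmyc(t)
        flat = [leaf for e in fit.entities for leaf in e]
        assert sorted(flat) == sorted(t.leaf_labels())

    def test_branch_rescaling_invariance(self):
        t = two_clade_tree()
        fit1 = fit_gmyc(t)
        scaled = UltrametricTree.from_newick(_scale_newick(t, 12.5))
        fit2 = fit_gmyc(scaled)
        assert fit1.n_clusters == fit2.n_clusters
        assert fit2.lrt_stat == pytest.approx(fit1.lrt_stat, abs=1e-5)
        assert fit2.threshold_height == pytest.approx(12.5 * fit1.threshold_height,
                                                      rel=1e-6)

    def test_null_exponent_recovery_on_coalescent_trees(self):
        # single-population Kingman trees: the fitted scaling exponent of
        # the coalescent rate should center on its true value 1
        cfg = SimConfig(seed=0, tau=0.0, theta=0.01)
        labels = {f"x{i:02d}": "northern" for i in range(20)}
        rng = np.random.default_rng(5)
        p0s = [
            fit_null(simulate_genealogy(labels, cfg, rng))[1] for _ in range(100)
        ]
        assert 0.7 <= np.median(p0s) <= 1.3

    def test_too_small_tree_rejected(self):
        t = UltrametricTree.from_newick("(A:1,B:1);")
        with pytest.raises(TooSmallError):
            fit_gmyc(t)
        with pytest.raises(TooSmallError):
            fit_null(t)

    def test_panmictic_tree_usually_single_cluster(self):
        cfg = SimConfig(seed=0, tau=0.0, theta=0.005)
        rng = np.random.default_rng(6)
        labels = {f"x{i:02d}": "northern" for i in range(20)}
        t = simulate_genealogy(labels, cfg, rng)
        fit = fit_gmyc(t)
        assert fit.p_value > 0.0  # a valid probability, not a hard zero


class TestLrtPvalue:
    def test_boundaries_and_monotonicity(self):
        assert lrt_pvalue(0.0, 3) == 1.0
        stats = [1.0, 5.0, 10.0, 50.0]
        ps = [lrt_pvalue(s, 3) for s in stats]
        assert all(b < a for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-8

    @pytest.mark.parametrize("stat", [1.0, 5.0, 10.0])
    @pytest.mark.parametrize("df", [2, 3])
    def test_matches_independent_chi2_tail(self, stat, df):
        from math import gamma

        def pdf(x):
            return x ** (df / 2 - 1) * np.exp(-x / 2) / (2 ** (df / 2) * gamma(df / 2))

        ref, _ = quad(pdf, stat, np.inf)
        assert lrt_pvalue(stat, df) == pytest.approx(ref, abs=1e-10)

    def test_negative_stat_rejected(self):
        with pytest.raises(GmycError):
            lrt_pvalue(-0.1)
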