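import numpy as np
import pytest

from discretus import synthetic_data as sd
from discretus.errors import DomainError, InsufficientDataError
from discretus.gmyc import (
    extract_partition,
    fit_gmyc,
    gmyc_likelihood,
    null_likelihood,
    partition_at_threshold,
    subsample_refit,
)
from discretus.io_core import UltrametricTree


def well_separated_tree(seed: int, n_clusters: int = 5, tips: int = 10):
    """Old species divergences, shallow crowns: unambiguous clusters."""
    rng = np.random.default_rng(seed)
    spt = sd.simulate_bd_tree(0.05, 0.0, n_clusters, rng)
    youngest = spt.branching_times()[-1]
    gene, truth = sd.simulate_gene_tree(spt, youngest / 20.0, tips, rng)
    return gene, truth


# ---------------------------------------------------------------------------
# independent oracle: direct per-segment summation over the tree itself
# ---------------------------------------------------------------------------

def oracle_loglik(
    tree: UltrametricTree, T: float, lam_d, p_d, lam_c, p_c
) -> float:
    """Brute-force evaluation: scans edges crossing each segment midpoint
    and groups sub-threshold lineages by their crossing ancestor."""
    dt = tree.dendropy_tree
    nodes = list(dt.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    ages = {n: tree.age(n) for n in nodes}

    def crossing_edges(t):
        out = []
        for n in nodes:
            if n.parent_node is None:
                continue
            if ages[n] < t < ages[n.parent_node]:
                out.append(n)
        return out

    def founder(node):
        # walk rootward to the node founding this sub-threshold cluster
        cur = node
        while cur.parent_node is not None and ages[cur.parent_node] < T:
            cur = cur.parent_node
        return id(cur)

    def hazard(t):
        edges = crossing_edges(t)
        if t > T:
            return lam_d * len(edges) ** p_d
        clusters: dict = {}
        for e in edges:
            clusters[founder(e)] = clusters.get(founder(e), 0) + 1
        coal = sum(
            (c * (c - 1.0)) ** p_c for c in clusters.values() if c >= 2
        )
        # the crossing species lineages keep diversification exposure
        n_species = len(crossing_edges(T))
        return lam_c * coal + lam_d * n_species**p_d

    def event_rate(node):
        t = ages[node] - 1e-12
        edges = crossing_edges(t)
        if ages[node] > T:
            return lam_d * len(edges) ** p_d
        clusters: dict = {}
        for e in edges:
            clusters[founder(e)] = clusters.get(founder(e), 0) + 1
        return lam_c * sum(
            (c * (c - 1.0)) ** p_c for c in clusters.values() if c >= 2
        )

    bounds = sorted({ages[n] for n in internal} | {0.0, T})
    loglik = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (lo + hi)
        loglik -= hazard(mid) * (hi - lo)
    for node in internal:
        loglik += np.log(event_rate(node))
    return loglik


class TestLikelihood:
    def test_matches_oracle_on_simulated_trees(self):
        for seed in range(4):
            gene, _ = well_separated_tree(seed, n_clusters=3, tips=4)
            root = gene.root_age
            for T in (0.3 * root, 0.6 * root, 0.9 * root):
                params = {
                    "lambda_div": 0.4,
                    "p_div": 1.2,
                    "lambda_coal": 3.0,
                    "p_coal": 0.8,
                }
                got = gmyc_likelihood(gene, T, params)
                want = oracle_loglik(gene, T, 0.4, 1.2, 3.0, 0.8)
                assert got == pytest.approx(want, rel=1e-9)

    def test_unified_bookkeeping_reduces_to_null(self):
        gene, _ = well_separated_tree(7)
        bt = gene.branching_times()
        T = 0.5 * (bt[1] + bt[2])
        for lam, p in [(0.5, 1.0), (2.0, 0.3)]:
            uni = gmyc_likelihood(
                gene,
                T,
                {
                    "lambda_div": lam,
                    "p_div": p,
                    "lambda_coal": lam,
                    "p_coal": p,
                },
                unified_bookkeeping=True,
            )
            assert uni == pytest.approx(
                null_likelihood(gene, lam, p), rel=1e-10
            )

    def test_threshold_domain_error(self, balanced4_tree):
        params = dict(lambda_div=1, p_div=1, lambda_coal=1, p_coal=1)
        with pytest.raises(DomainError):
            gmyc_likelihood(balanced4_tree, -1.0, params)
        with pytest.raises(DomainError):
            gmyc_likelihood(balanced4_tree, 10.0, params)

    def test_loglik_degrades_at_extreme_rates(self):
        gene, _ = well_separated_tree(3)
        T = float(np.median(gene.branching_times()))

        def ll(lam):
            return gmyc_likelihood(
                gene,
                T,
                {
                    "lambda_div": lam,
                    "p_div": 1.0,
                    "lambda_coal": lam,
                    "p_coal": 1.0,
                },
            )

        mid = ll(1.0)
        assert np.isfinite(mid)
        assert ll(1e-8) < mid
        assert ll(1e6) < mid


class TestFit:
    def test_constructed_truth_recovery(self):
        gene, truth = well_separated_tree(1)
        fit = fit_gmyc(gene)
        assert fit.n_entities == 5
        assert fit.p_value < 0.05
        part = extract_partition(fit, gene)
        # clusters coincide with the true species map
        grouped = {
            sp: sorted(tips) for sp, tips in part.clusters.items()
        }
        true_groups = {}
        for tip, species in truth.items():
            true_groups.setdefault(species, []).append(tip)
        assert sorted(map(tuple, grouped.values())) == sorted(
            tuple(sorted(v)) for v in true_groups.values()
        )

    def test_nesting_invariant(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            sub = sd._coalescent_subtree(
                [f"t{i}" for i in range(12)], 1.0, rng, None
            )
            tree = sd._to_ultrametric(sub)
            fit = fit_gmyc(tree)
            assert fit.loglik_gmyc >= fit.loglik_null - 1e-9
            assert fit.lr_chi2 >= 0.0

    def test_small_tree_rejected(self, simple_tree):
        with pytest.raises(InsufficientDataError):
            fit_gmyc(simple_tree)

    def test_df_conventions(self):
        gene, _ = well_separated_tree(2)
        f2 = fit_gmyc(gene, df=2)
        f3 = fit_gmyc(gene, df=3)
        assert f2.lr_chi2 == pytest.approx(f3.lr_chi2)
        assert f3.p_value >= f2.p_value

    def test_threshold_scale_invariance(self):
        gene, _ = well_separated_tree(4)
        fit = fit_gmyc(gene)
        scaled = fit_gmyc(gene.rescale(3.0))
        assert scaled.threshold_T == pytest.approx(3.0 * fit.threshold_T)
        assert scaled.n_entities == fit.n_entities
        assert scaled.lr_chi2 == pytest.approx(fit.lr_chi2, abs=1e-6)
        assert scaled.lambda_coal == pytest.approx(
            fit.lambda_coal / 3.0, rel=1e-4
        )

    def test_type_one_error_band_small(self):
        # light version of the calibration (full run in acceptance tests)
        rej = 0
        n = 120
        for seed in range(n):
            rng = np.random.default_rng(10_000 + seed)
            tree = sd._to_ultrametric(
                sd._coalescent_subtree(
                    [f"t{i}" for i in range(20)], 1.0, rng, None
                )
            )
            rej += fit_gmyc(tree).p_value < 0.05
        assert 0.0 < rej / n < 0.15


class TestPartition:
    def test_threshold_below_all_nodes_all_singletons(self, balanced4_tree):
        part = partition_at_threshold(balanced4_tree, 0.5)
        assert part.n_entities == 4
        assert len(part.singletons) == 4

    def test_threshold_above_all_nodes_one_cluster(self, balanced4_tree):
        part = partition_at_threshold(balanced4_tree, 3.0)
        assert part.n_entities == 1
        assert sorted(part.clusters["sp1"]) == ["A", "B", "C", "D"]

    def test_partition_is_exhaustive_and_disjoint(self):
        gene, _ = well_separated_tree(6)
        fit = fit_gmyc(gene)
        part = extract_partition(fit, gene)
        tips = [t for v in part.clusters.values() for t in v]
        assert sorted(tips) == sorted(gene.tip_labels)
        assert len(tips) == len(set(tips))
        # cluster with >= 2 tips iff its mrca is younger than the threshold
        for sp, members in part.clusters.items():
            if len(members) >= 2:
                assert gene.mrca_age(members) < fit.threshold_T


class TestSubsampleRefit:
    def test_fraction_one_is_identity(self):
        gene, _ = well_separated_tree(8)
        full = fit_gmyc(gene)
        summary = subsample_refit(gene, 1.0, 3, seed=0)
        assert np.allclose(summary.p_values, full.p_value)
        assert np.all(summary.n_entities == full.n_entities)

    def test_zero_reps(self):
        gene, _ = well_separated_tree(8)
        summary = subsample_refit(gene, 0.5, 0, seed=0)
        assert summary.p_values.size == 0
        assert np.isnan(summary.mean_p_value)

    def test_sparse_degrades_faster_than_saturated(self):
        # sparse: 2-3 tips per cluster; saturated: 12 per cluster
        rng = np.random.default_rng(77)
        spt = sd.simulate_bd_tree(0.05, 0.0, 5, rng)
        depth = spt.branching_times()[-1] / 10.0
        sparse_counts = {
            lab: int(c)
            for lab, c in zip(spt.tip_labels, rng.integers(2, 4, 5))
        }
        sparse, _ = sd.simulate_gene_tree(spt, depth, sparse_counts, rng)
        saturated, _ = sd.simulate_gene_tree(spt, depth, 15, rng)
        s1 = subsample_refit(sparse, 0.5, 15, seed=1)
        s2 = subsample_refit(saturated, 0.5, 15, seed=1)
        assert s1.mean_p_value > s2.mean_p_value
        assert np.mean(s1.p_values > 0.05) > np.mean(s2.p_values > 0.05)

    def test_bad_fraction(self):
        gene, _ = well_separated_tree(8)
        with pytest.raises(DomainError):
            subsample_refit(gene, 1.5, 2, seed=0)
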