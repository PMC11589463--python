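import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import motorscn as m
from motorscn.inference import _perm_p, _threshold_mask, suprathreshold_components
import _oracles as oracle


def _net(z, n_subjects, k=3, group="g", nodes=None):
    nodes = nodes or [f"n{i}" for i in range(z.shape[0])]
    return m.CovarianceNetwork(group, nodes, np.tanh(z), z, n_subjects, k)


class TestEdgeStatistic:
    def test_identical_networks_give_zero(self, rng):
        z = rng.normal(0, 0.3, (6, 6))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        stat = m.edge_statistic(_net(z, 27), _net(z, 38))
        assert np.allclose(stat, 0.0)

    def test_closed_form_value(self):
        """zA - zB = 0.8 at nA=27, nB=38, k=3:
        stat = 0.8 / sqrt(1/21 + 1/32) = 2.8486."""
        zA = np.array([[0, 0.9], [0.9, 0]])
        zB = np.array([[0, 0.1], [0.1, 0]])
        stat = m.edge_statistic(_net(zA, 27), _net(zB, 38))
        assert stat[0, 1] == pytest.approx(0.8 / np.sqrt(1 / 21 + 1 / 32))
        assert stat[0, 1] == pytest.approx(2.8486, abs=1e-4)

    def test_swapping_groups_negates_matrix(self, rng):
        zA = rng.normal(0, 0.3, (5, 5)); zA = (zA + zA.T) / 2; np.fill_diagonal(zA, 0)
        zB = rng.normal(0, 0.3, (5, 5)); zB = (zB + zB.T) / 2; np.fill_diagonal(zB, 0)
        a, b = _net(zA, 27), _net(zB, 38)
        assert np.allclose(m.edge_statistic(a, b), -m.edge_statistic(b, a))

    def test_too_small_group_rejected(self):
        z = np.zeros((3, 3))
        with pytest.raises(ValueError, match="too small"):
            m.edge_statistic(_net(z, 6, k=3), _net(z, 38, k=3))


class TestComponents:
    @pytest.mark.parametrize("case", range(25))
    def test_matches_union_find_oracle(self, case):
        """Component extraction on random 20-node statistic matrices equals
        an independent union-find over the suprathreshold edges."""
        rng = np.random.default_rng(case)
        stat = rng.normal(0, 2, (20, 20))
        stat = (stat + stat.T) / 2
        np.fill_diagonal(stat, 0)
        mask = _threshold_mask(stat, 3.1, "greater")
        ours = suprathreshold_components(mask)
        theirs = oracle.union_find_components(mask.tolist())
        assert sorted(map(sorted, ours)) == sorted(map(sorted, theirs))

    def test_empty_mask_gives_no_components(self):
        assert suprathreshold_components(np.zeros((5, 5), dtype=bool)) == []


class TestNBS:
    def test_infinite_threshold_empty_result(self, two_group_cohort):
        cfg = m.RunConfig(nbs_stat_threshold=np.inf, n_perm_nbs=10)
        res = m.nbs(two_group_cohort, ("pPVL", "HC"), cfg, rng=0)
        for r in res.values():
            assert r.components == []
            assert r.observed_max_size == 0
            assert r.min_fwe_p == 1.0

    def test_deterministic_under_fixed_seed(self, two_group_cohort):
        cfg = m.RunConfig(n_perm_nbs=50)
        a = m.nbs(two_group_cohort, ("pPVL", "HC"), cfg, rng=9)
        b = m.nbs(two_group_cohort, ("pPVL", "HC"), cfg, rng=9)
        for d in ("greater", "less"):
            assert np.array_equal(a[d].null_max_sizes, b[d].null_max_sizes)
            assert a[d].components == b[d].components

    def test_fwe_p_respects_plus_one_bound(self, two_group_cohort):
        cfg = m.RunConfig(n_perm_nbs=20, nbs_stat_threshold=0.5)
        res = m.nbs(two_group_cohort, ("pPVL", "HC"), cfg, rng=3)
        for r in res.values():
            for c in r.components:
                assert c["fwe_p"] >= 1 / 21

    def test_per_group_residual_scope_runs(self, two_group_cohort):
        cfg = m.RunConfig(n_perm_nbs=5, residual_scope="per-group")
        res = m.nbs(two_group_cohort, ("pPVL", "HC"), cfg, rng=1)
        assert set(res) == {"greater", "less"}


class TestPermutationP:
    def test_n_perm_one_boundary(self):
        assert _perm_p(np.array([1.0]), 2.0, "greater") == pytest.approx(0.5)
        assert _perm_p(np.array([5.0]), 2.0, "greater") == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(1, 200), seed=st.integers(0, 999))
    def test_plus_one_lower_bound(self, n, seed):
        rng = np.random.default_rng(seed)
        null = rng.normal(0, 1, n)
        p = _perm_p(null, 10.0, "greater")
        assert 1 / (1 + n) <= p <= 1.0


class TestCompareMetrics:
    def test_boundary_n_perm_one(self, two_group_cohort):
        cfg = m.RunConfig(n_perm_metrics=1)
        out = m.compare_metrics(two_group_cohort, ("pPVL", "HC"), cfg,
                                global_names=("global_efficiency",),
                                nodal_names=(), rng=0)
        assert out[0].p_raw in (0.5, 1.0)

    def test_nodal_fdr_applied_within_metric(self, two_group_cohort):
        cfg = m.RunConfig(n_perm_metrics=20)
        out = m.compare_metrics(two_group_cohort, ("pPVL", "HC"), cfg,
                                global_names=(), nodal_names=("degree",), rng=1)
        assert len(out) == 20
        assert all(o.scope == "nodal" and o.p_fdr is not None for o in out)
        # BH never decreases the raw p below itself
        assert all(o.p_fdr >= o.p_raw - 1e-12 for o in out)

    def test_implanted_topology_difference_detected(self):
        """Control covariance strongly modular by region class, patient
        covariance unstructured: at matched densities the patient graphs are
        more integrated, and the AUC global-efficiency permutation test
        flags the difference."""
        import pandas as pd
        atlas = m.motor_atlas()
        modular = m.default_base_corr(atlas, within=0.7, between=0.1)
        flat = m.default_base_corr(atlas, within=0.4, between=0.4)
        hc = m.simulate_cohort(m.SimulationSpec(
            group_sizes={"HC": 200}, base_corr=modular, edge_deltas=[],
            atrophy=[], n_extra_rois=0, seed=21))
        pat = m.simulate_cohort(m.SimulationSpec(
            group_sizes={"pPVL": 200}, base_corr=flat, edge_deltas=[],
            atrophy=[], n_extra_rois=0, seed=22))
        df = pd.concat([hc.data, pat.data], ignore_index=True)
        merged = m.CohortTable(df, atlas, [], hc.score_columns)
        cfg = m.RunConfig(n_perm_metrics=199)
        out = m.compare_metrics(merged, ("pPVL", "HC"), cfg,
                                global_names=("global_efficiency",),
                                nodal_names=(), rng=5)
        assert out[0].p_raw < 0.05
        assert out[0].observed_diff > 0


class TestHubs:
    def test_arithmetic_example(self):
        """degrees [10,10,10,10,30]: mean 14, population SD 8, cutoff 22."""
        hubs = m.identify_hubs(np.array([10, 10, 10, 10, 30.0]),
                               ["a", "b", "c", "d", "e"])
        assert hubs == {"e"}

    def test_all_equal_degrees_no_hubs(self):
        assert m.identify_hubs(np.full(6, 4.0), list("abcdef")) == set()

    def test_zero_multiplier_selects_strictly_above_mean(self):
        vals = np.array([1.0, 2.0, 3.0])
        assert m.identify_hubs(vals, ["a", "b", "c"], sd_multiplier=0.0) == {"c"}

    def test_classification_set_algebra(self):
        rep = m.classify_hubs({"A", "C"}, {"A", "B"})
        assert rep.preserved == {"A"}
        assert rep.lost == {"B"}
        assert rep.reconfigured == {"C"}
        assert not (rep.preserved & rep.lost & rep.reconfigured)

    def test_identical_hub_sets(self):
        rep = m.classify_hubs({"A", "B"}, {"A", "B"})
        assert rep.lost == set() and rep.reconfigured == set()
        assert rep.preserved == {"A", "B"}

    def test_hub_analysis_pipeline_runs(self, two_group_cohort):
        cfg = m.RunConfig()
        rep = m.hub_analysis(two_group_cohort, "pPVL", "HC", cfg)
        assert rep.preserved | rep.reconfigured == rep.patient_hubs
        assert rep.preserved | rep.lost == rep.reference_hubs


class TestSpecificity:
    @staticmethod
    def _whole_brain_network(seed=0, n=100, inflate=True):
        atlas = m.motor_atlas()
        base = (m.default_base_corr(atlas) if inflate
                else m.default_base_corr(atlas, within=0.25, between=0.25))
        spec = m.SimulationSpec(group_sizes={"HC": n}, base_corr=base,
                                edge_deltas=[], atrophy=[], n_extra_rois=70,
                                extra_corr=0.25, extra_motor_corr=0.2, seed=seed)
        cohort = m.simulate_cohort(spec)
        resid = m.residualize(cohort, groups=["HC"], include_extras=True)
        return m.build_group_network(resid["HC"]), atlas

    def test_single_random_set_boundary(self):
        net, atlas = self._whole_brain_network()
        cfg = m.RunConfig(n_random_sets=1)
        res = m.specificity_test(net, atlas.names, cfg, rng=0)
        assert res.p_greater in (0.5, 1.0)
        assert res.p_less in (0.5, 1.0)

    def test_inflated_motor_block_detected(self):
        net, atlas = self._whole_brain_network(seed=3, n=150)
        cfg = m.RunConfig(n_random_sets=500)
        res = m.specificity_test(net, atlas.names, cfg, rng=1)
        assert res.p_greater < 0.05

    def test_pool_smaller_than_subset_rejected(self):
        net, atlas = self._whole_brain_network()
        small = m.CovarianceNetwork("HC", net.nodes[:25], net.r_matrix[:25, :25],
                                    net.z_matrix[:25, :25], net.n_subjects, 3)
        cfg = m.RunConfig(n_random_sets=10)
        with pytest.raises(ValueError, match="pool"):
            m.specificity_test(small, atlas.names, cfg, rng=0)

    def test_include_motor_pool_flag(self):
        net, atlas = self._whole_brain_network()
        cfg = m.RunConfig(n_random_sets=50, specificity_pool="include_motor")
        res = m.specificity_test(net, atlas.names, cfg, rng=2)
        assert 0 < res.p_greater <= 1

    def test_deterministic_under_seed(self):
        net, atlas = self._whole_brain_network()
        cfg = m.RunConfig(n_random_sets=100)
        a = m.specificity_test(net, atlas.names, cfg, rng=7)
        b = m.specificity_test(net, atlas.names, cfg, rng=7)
        assert np.array_equal(a.null_means, b.null_means)
        assert a.p_greater == b.p_greater
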