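"""Permutation-based inference on structural covariance networks.

* Network-based statistic (NBS): edge-wise Fisher-z difference statistics,
  suprathreshold connected components, family-wise error control by
  permuting group labels and recording the null maximum component size.
* Global/nodal graph-metric comparisons on density-AUC values with
  label-permutation p-values and Benjamini-Hochberg correction across nodes.
* Hub identification (degree centrality > mean + k x SD) and
  preserved / lost / reconfigured classification against a reference group.
* Specificity test: mean motor-network covariance against random equal-size
  node subsets from a whole-brain ROI pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .io import COVARIATES, CohortTable, RunConfig
from .network import (CovarianceNetwork, ResidualMatrix, build_group_network,
                      residualize, sweep_densities)
from . import metrics as gm

logger = logging.getLogger("motorscn")


def _as_rng(rng: np.random.Generator | int | None, config: RunConfig | None = None
            ) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None and config is not None:
        rng = config.rng_seed
    return np.random.default_rng(rng)


def _perm_p(null: np.ndarray, observed: float, tail: str = "greater") -> float:
    """Permutation p with the +1 correction: p >= 1/(1 + n_perm)."""
    null = np.asarray(null, dtype=float)
    if tail == "greater":
        hits = int((null >= observed).sum())
    elif tail == "less":
        hits = int((null <= observed).sum())
    else:  # two-sided on magnitudes
        hits = int((np.abs(null) >= abs(observed)).sum())
    return (1 + hits) / (1 + len(null))


# ---------------------------------------------------------------------------
# Edge statistic and NBS
# ---------------------------------------------------------------------------

def edge_statistic(netA: CovarianceNetwork, netB: CovarianceNetwork) -> np.ndarray:
    """Fisher-z difference statistic per edge.

    stat = (zA - zB) / sqrt(1/(nA - 3 - k) + 1/(nB - 3 - k)), where k is the
    number of covariates residualised out before the correlations were taken.
    Asymptotically standard normal per edge under equality of covariance.
    """
    if netA.nodes != netB.nodes:
        raise ValueError("networks must share an identical node set/order")
    k = netA.df_adjustment
    if netB.df_adjustment != k:
        raise ValueError("networks built with different covariate sets")
    dfA, dfB = netA.n_subjects - 3 - k, netB.n_subjects - 3 - k
    if dfA <= 0 or dfB <= 0:
        raise ValueError(
            f"group too small for z-difference statistic (df {dfA}, {dfB})")
    se = np.sqrt(1.0 / dfA + 1.0 / dfB)
    stat = (netA.z_matrix - netB.z_matrix) / se
    np.fill_diagonal(stat, 0.0)
    return stat


def _threshold_mask(stat: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    if direction == "greater":
        mask = stat > threshold
    elif direction == "less":
        mask = stat < -threshold
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    np.fill_diagonal(mask, False)
    return mask


def suprathreshold_components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """Connected components of the suprathreshold graph, as edge lists.

    Components with zero edges (isolated nodes) are dropped.
    """
    n = mask.shape[0]
    iu, ju = np.nonzero(np.triu(mask, k=1))
    if len(iu) == 0:
        return []
    g = sparse.csr_matrix((np.ones(len(iu)), (iu, ju)), shape=(n, n))
    n_comp, labels = connected_components(g, directed=False)
    comps: dict[int, list[tuple[int, int]]] = {}
    for i, j in zip(iu.tolist(), ju.tolist()):
        comps.setdefault(labels[i], []).append((i, j))
    return sorted(comps.values(), key=len, reverse=True)


def _max_component_edges(mask: np.ndarray) -> int:
    comps = suprathreshold_components(mask)
    return len(comps[0]) if comps else 0


@dataclass
class NBSResult:
    group_pair: tuple[str, str]
    direction: str                      # 'greater': A > B
    edge_stat_matrix: np.ndarray
    stat_threshold: float
    components: list[dict]              # {'edges': [(name, name)...], 'size': int, 'fwe_p': float}
    observed_max_size: int
    null_max_sizes: np.ndarray
    n_perm: int
    nodes: list[str] = field(default_factory=list)

    @property
    def min_fwe_p(self) -> float:
        return min((c["fwe_p"] for c in self.components), default=1.0)

    def significant_edges(self, alpha: float = 0.05) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for c in self.components:
            if c["fwe_p"] <= alpha:
                out.update(tuple(e) for e in c["edges"])
        return out


def _networks_for_labels(values: np.ndarray, labels: np.ndarray,
                         groups: tuple[str, str], nodes: list[str],
                         k_cov: int) -> tuple[CovarianceNetwork, CovarianceNetwork]:
    nets = []
    for g in groups:
        rows = values[labels == g]
        res = ResidualMatrix(g, [], nodes, rows, ["_"] * k_cov)
        nets.append(build_group_network(res))
    return nets[0], nets[1]


def nbs(cohort: CohortTable, groups: tuple[str, str], config: RunConfig,
        rng: np.random.Generator | int | None = None,
        directions: Sequence[str] = ("greater", "less"),
        covariates: Sequence[str] = COVARIATES) -> dict[str, NBSResult]:
    """Network-based statistic between two groups, both directions.

    Group labels are permuted and the full pipeline (residualisation within
    the permuted design, network construction, edge statistic, component
    extraction) is recomputed per permutation; with the default pooled
    residualisation the residuals are label-invariant, so only the
    row-to-group assignment is re-drawn.
    """
    rng = _as_rng(rng, config)
    sub = cohort.subset(groups)
    resid = residualize(sub, covariates=covariates, scope=config.residual_scope,
                        groups=groups)
    netA, netB = (build_group_network(resid[g]) for g in groups)
    stat = edge_statistic(netA, netB)
    nodes = netA.nodes
    thr = config.nbs_stat_threshold

    observed = {d: suprathreshold_components(_threshold_mask(stat, thr, d))
                for d in directions}

    labels = sub.data["group"].to_numpy()
    k_cov = netA.df_adjustment
    pooled = config.residual_scope == "pooled"
    if pooled:
        all_values = np.concatenate([resid[groups[0]].values,
                                     resid[groups[1]].values], axis=0)
        all_labels = np.concatenate([np.repeat(groups[0], netA.n_subjects),
                                     np.repeat(groups[1], netB.n_subjects)])

    n_perm = config.n_perm_nbs
    null_max = {d: np.empty(n_perm, dtype=int) for d in directions}
    for p in range(n_perm):
        if pooled:
            perm_labels = all_labels[rng.permutation(len(all_labels))]
            pA, pB = _networks_for_labels(all_values, perm_labels, groups,
                                          nodes, k_cov)
        else:
            perm = rng.permutation(len(labels))
            perm_df = sub.data.copy()
            perm_df["group"] = labels[perm]
            perm_cohort = CohortTable(perm_df, sub.atlas, sub.extra_nodes,
                                      sub.score_columns)
            perm_res = residualize(perm_cohort, covariates=covariates,
                                   scope="per-group", groups=groups)
            pA, pB = (build_group_network(perm_res[g]) for g in groups)
        pstat = edge_statistic(pA, pB)
        for d in directions:
            null_max[d][p] = _max_component_edges(_threshold_mask(pstat, thr, d))

    results = {}
    for d in directions:
        comps = []
        for edges in observed[d]:
            size = len(edges)
            comps.append({
                "edges": [(nodes[i], nodes[j]) for i, j in edges],
                "size": size,
                "fwe_p": _perm_p(null_max[d], size, "greater"),
            })
        results[d] = NBSResult(
            group_pair=groups, direction=d, edge_stat_matrix=stat,
            stat_threshold=thr, components=comps,
            observed_max_size=max((c["size"] for c in comps), default=0),
            null_max_sizes=null_max[d], n_perm=n_perm, nodes=list(nodes))
    return results


# ---------------------------------------------------------------------------
# Metric comparisons (AUC over the density sweep)
# ---------------------------------------------------------------------------

@dataclass
class MetricComparison:
    metric: str
    scope: str                  # 'global' | 'nodal'
    node: str | None
    observed_diff: float        # group A - group B, AUC scale
    p_raw: float
    p_fdr: float | None = None
    n_perm: int = 0


def _auc_bundle(values: np.ndarray, nodes: list[str], grid: np.ndarray,
                global_names: tuple[str, ...], nodal_names: tuple[str, ...],
                partition: np.ndarray | None, k_cov: int,
                ranking: str) -> tuple[dict, dict]:
    res = ResidualMatrix("_", [], nodes, values, ["_"] * k_cov)
    net = build_group_network(res)
    sweep = sweep_densities(net, grid, ranking=ranking)
    g = gm.auc_global_metrics(sweep.graphs, grid, global_names) if global_names else {}
    n = (gm.auc_nodal_metrics(sweep.graphs, grid, partition, nodal_names)
         if nodal_names else {})
    return g, n


def compare_metrics(cohort: CohortTable, groups: tuple[str, str],
                    config: RunConfig,
                    global_names: tuple[str, ...] = gm.GLOBAL_METRIC_NAMES,
                    nodal_names: tuple[str, ...] = ("degree", "betweenness",
                                                    "clustering", "local_efficiency"),
                    rng: np.random.Generator | int | None = None,
                    covariates: Sequence[str] = COVARIATES) -> list[MetricComparison]:
    """Two-sided permutation tests on AUC-averaged metrics (group A - B);
    nodal p-values are Benjamini-Hochberg corrected across nodes per metric."""
    rng = _as_rng(rng, config)
    sub = cohort.subset(groups)
    grid = config.density_grid
    partition = cohort.atlas.region_classes
    resid = residualize(sub, covariates=covariates, scope=config.residual_scope,
                        groups=groups)
    nodes = resid[groups[0]].nodes
    k_cov = len(resid[groups[0]].covariates_used)

    def bundle(values):
        return _auc_bundle(values, nodes, grid, global_names, nodal_names,
                           partition, k_cov, config.edge_ranking)

    gA, nA = bundle(resid[groups[0]].values)
    gB, nB = bundle(resid[groups[1]].values)
    obs_g = {m: gA[m] - gB[m] for m in global_names}
    obs_n = {m: nA[m] - nB[m] for m in nodal_names}

    all_values = np.concatenate([resid[groups[0]].values,
                                 resid[groups[1]].values], axis=0)
    nA_subj = resid[groups[0]].values.shape[0]
    n_perm = config.n_perm_metrics
    null_g = {m: np.empty(n_perm) for m in global_names}
    null_n = {m: np.empty((n_perm, len(nodes))) for m in nodal_names}
    for p in range(n_perm):
        perm = rng.permutation(all_values.shape[0])
        pg_a, pn_a = bundle(all_values[perm[:nA_subj]])
        pg_b, pn_b = bundle(all_values[perm[nA_subj:]])
        for m in global_names:
            null_g[m][p] = pg_a[m] - pg_b[m]
        for m in nodal_names:
            null_n[m][p] = pn_a[m] - pn_b[m]

    out: list[MetricComparison] = []
    for m in global_names:
        null = null_g[m]
        if np.ptp(np.append(null, obs_g[m])) == 0:
            logger.warning("degenerate permutation distribution for %s; p = 1", m)
            p_raw = 1.0
        else:
            p_raw = _perm_p(null, obs_g[m], "two-sided")
        out.append(MetricComparison(m, "global", None, float(obs_g[m]),
                                    p_raw, None, n_perm))
    for m in nodal_names:
        praws = np.array([_perm_p(null_n[m][:, i], obs_n[m][i], "two-sided")
                          for i in range(len(nodes))])
        _, pfdr, *_ = multipletests(praws, method="fdr_bh")
        for i, node in enumerate(nodes):
            out.append(MetricComparison(m, "nodal", node, float(obs_n[m][i]),
                                        float(praws[i]), float(pfdr[i]), n_perm))
    return out


# ---------------------------------------------------------------------------
# Hubs
# ---------------------------------------------------------------------------

@dataclass
class HubReport:
    patient_group: str
    reference_group: str
    patient_hubs: set[str]
    reference_hubs: set[str]
    preserved: set[str]
    lost: set[str]
    reconfigured: set[str]


def identify_hubs(values: np.ndarray, nodes: Sequence[str],
                  sd_multiplier: float = 1.0) -> set[str]:
    """Nodes whose (AUC-averaged) degree centrality exceeds the network mean
    by ``sd_multiplier`` population standard deviations."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two nodes")
    sd = values.std()   # population SD over the node set
    if sd == 0:
        logger.warning("zero SD of hub statistic; no hubs identified")
        return set()
    cutoff = values.mean() + sd_multiplier * sd
    return {nodes[i] for i in np.flatnonzero(values > cutoff)}


def classify_hubs(patient_hubs: set[str], reference_hubs: set[str],
                  patient_group: str = "patient",
                  reference_group: str = "reference") -> HubReport:
    """preserved = both; lost = reference only; reconfigured = patient only."""
    return HubReport(
        patient_group=patient_group, reference_group=reference_group,
        patient_hubs=set(patient_hubs), reference_hubs=set(reference_hubs),
        preserved=set(patient_hubs) & set(reference_hubs),
        lost=set(reference_hubs) - set(patient_hubs),
        reconfigured=set(patient_hubs) - set(reference_hubs))


def group_hub_statistic(cohort: CohortTable, group: str, config: RunConfig,
                        covariates: Sequence[str] = COVARIATES) -> tuple[np.ndarray, list[str]]:
    """AUC-averaged hub statistic per node for one group: degree centrality
    (default) or participation coefficient (config.hub_rule)."""
    resid = residualize(cohort, covariates=covariates,
                        scope=config.residual_scope, groups=[group])
    net = build_group_network(resid[group])
    sweep = sweep_densities(net, config.density_grid, ranking=config.edge_ranking)
    if config.hub_rule == "participation":
        auc = gm.auc_nodal_metrics(sweep.graphs, config.density_grid,
                                   partition=cohort.atlas.region_classes,
                                   metrics=("participation",))["participation"]
    else:
        auc = gm.auc_nodal_metrics(sweep.graphs, config.density_grid,
                                   metrics=("degree",))["degree"]
    return auc, net.nodes


def hub_analysis(cohort: CohortTable, patient_group: str, reference_group: str,
                 config: RunConfig) -> HubReport:
    stat_p, nodes = group_hub_statistic(cohort, patient_group, config)
    stat_r, _ = group_hub_statistic(cohort, reference_group, config)
    hubs_p = identify_hubs(stat_p, nodes, config.hub_sd_multiplier)
    hubs_r = identify_hubs(stat_r, nodes, config.hub_sd_multiplier)
    return classify_hubs(hubs_p, hubs_r, patient_group, reference_group)


# ---------------------------------------------------------------------------
# Motor-network specificity test
# ---------------------------------------------------------------------------

@dataclass
class SpecificityResult:
    observed_mean_z: float
    null_means: np.ndarray
    p_greater: float
    p_less: float
    n_random_sets: int
    motor_nodes: list[str]


def specificity_test(net: CovarianceNetwork, motor_nodes: Sequence[str],
                     config: RunConfig,
                     rng: np.random.Generator | int | None = None
                     ) -> SpecificityResult:
    """Mean off-diagonal covariance (z) of the motor nodes versus random
    equal-sized node subsets from the whole-brain pool.

    The pool excludes the motor nodes by default (config.specificity_pool);
    one-sided p-values both ways with the +1 correction.
    """
    rng = _as_rng(rng, config)
    idx = {name: i for i, name in enumerate(net.nodes)}
    motor = np.array([idx[m] for m in motor_nodes])
    k = len(motor)

    if config.specificity_pool == "include_motor":
        pool = np.arange(len(net.nodes))
    else:
        pool = np.array([i for i in range(len(net.nodes)) if i not in set(motor)])
    if len(pool) < k:
        raise ValueError(f"node pool ({len(pool)}) smaller than subset size ({k})")

    z = net.z_matrix
    off = ~np.eye(k, dtype=bool)

    def mean_block(ids: np.ndarray) -> float:
        return float(z[np.ix_(ids, ids)][off].mean())

    observed = mean_block(motor)
    nulls = np.empty(config.n_random_sets)
    for s in range(config.n_random_sets):
        nulls[s] = mean_block(rng.choice(pool, size=k, replace=False))
    return SpecificityResult(
        observed_mean_z=observed, null_means=nulls,
        p_greater=_perm_p(nulls, observed, "greater"),
        p_less=_perm_p(nulls, observed, "less"),
        n_random_sets=config.n_random_sets, motor_nodes=list(motor_nodes))
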