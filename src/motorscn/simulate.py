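"""Synthetic cohort generation.

Emulates the statistical structure the structural-covariance analysis
assumes: three groups (preterm PVL, full-term PVL, healthy controls) of
children aged 1-8 years, 20 motor ROI volumes with a group-specific latent
correlation structure, confounding by age, sex and total intracranial volume,
thalamic atrophy in the patient groups, and gross-motor scores driven by
thalamic volume.  Correlation differences are implanted on the latent
(covariate-free) scale so that covariate residualisation recovers the target
structure exactly in expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .io import CohortTable, NodeAtlas, generic_atlas, motor_atlas

logger = logging.getLogger("motorscn")

#: plausible mean grey-matter volumes (ml) per motor region (paired L/R share)
_DEFAULT_REGION_MEANS = {
    "PrG": 12.0, "SMA": 8.0, "PoG": 10.0, "SPL": 9.0, "PaL": 4.0,
    "Cau": 4.0, "Put": 5.0, "Pal": 1.5, "Tha": 7.0, "Cer": 50.0,
}

#: healthy-control TIV ~1348 ml; preterm patients markedly smaller
_DEFAULT_TIV = {"HC": (1348.0, 150.0), "pPVL": (1156.0, 150.0),
                "fPVL": (1300.0, 150.0)}


def default_base_corr(atlas: NodeAtlas,
                      within: float = 0.6, between: float = 0.3) -> np.ndarray:
    """Block correlation: ``within`` inside a region class, ``between`` across.

    A synthetic convention (plausible for morphometric covariance, not an
    empirical estimate); positive definite for the defaults used here.
    """
    classes = atlas.region_classes
    same = classes[:, None] == classes[None, :]
    corr = np.where(same, within, between).astype(float)
    np.fill_diagonal(corr, 1.0)
    return corr


def default_edge_deltas(atlas: NodeAtlas) -> list[tuple[str, str, str, float]]:
    """Group-specific covariance offsets mirroring the disease contrast:
    weakened coupling of the central grey nuclei with cortex and cerebellum,
    strengthened cortex-cerebellum coupling; stronger in the preterm group.
    """
    classes = dict(zip(atlas.names, atlas.region_classes))
    deltas: list[tuple[str, str, str, float]] = []
    for group, weaken, strengthen in (("pPVL", -0.25, 0.25), ("fPVL", -0.15, 0.15)):
        for i, a in enumerate(atlas.names):
            for b in atlas.names[i + 1:]:
                ca, cb = classes[a], classes[b]
                pair = {ca, cb}
                if "basal_ganglia_thalamus" in pair and ca != cb:
                    deltas.append((a, b, group, weaken))
                elif pair == {"cortex", "cerebellum"}:
                    deltas.append((a, b, group, strengthen))
    return deltas


@dataclass
class ScoreModel:
    """Motor score as a linear function of one node's latent volume signal."""
    target_node: str = "LTha"
    slope: float = 8.0       # score points per latent SD of the target node
    noise_sd: float = 10.0
    intercept: float = 60.0


@dataclass
class CovariateEffects:
    """Fractional volume change per covariate unit (applied to node means)."""
    age: float = 0.03    # per year, centred at 4.5 y
    sex: float = 0.04    # male (1) minus female (0), centred at 0.5
    tiv: float = 0.05    # per standardised TIV unit


@dataclass
class SimulationSpec:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"pPVL": 27, "fPVL": 15, "HC": 38})
    atlas: NodeAtlas = field(default_factory=motor_atlas)
    base_mean: np.ndarray | None = None
    base_corr: np.ndarray | None = None
    edge_deltas: list[tuple[str, str, str, float]] = field(default_factory=list)
    atrophy: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("LTha", "pPVL", 0.15), ("RTha", "pPVL", 0.12),
                                 ("LTha", "fPVL", 0.08)])
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    score_model: ScoreModel = field(default_factory=ScoreModel)
    noise_sd: np.ndarray | float = 0.08   # residual SD as fraction of node mean
    tiv_by_group: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TIV))
    n_extra_rois: int = 70
    extra_corr: float = 0.25       # latent correlation among extra ROIs
    extra_motor_corr: float = 0.20  # latent correlation extras <-> motor nodes
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 4:
                raise ValueError(f"group {g!r} needs >= 4 subjects, got {n}")
        if self.base_mean is None:
            self.base_mean = np.array(
                [_DEFAULT_REGION_MEANS.get(n.name[1:], 10.0) for n in self.atlas.nodes])
        self.base_mean = np.asarray(self.base_mean, dtype=float)
        if self.base_corr is None:
            self.base_corr = default_base_corr(self.atlas)
        self.base_corr = np.asarray(self.base_corr, dtype=float)
        if np.isscalar(self.noise_sd):
            self.noise_sd = float(self.noise_sd) * self.base_mean
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if (self.noise_sd <= 0).any():
            raise ValueError("noise_sd must be positive")


class SimulationError(RuntimeError):
    pass


def nearest_positive_definite(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and renormalise to unit diagonal."""
    w, v = np.linalg.eigh((corr + corr.T) / 2.0)
    if w.min() >= floor:
        return corr
    logger.info("projecting correlation to positive definite (min eig %.3g)", w.min())
    w = np.clip(w, floor, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _group_correlation(spec: SimulationSpec, group: str) -> np.ndarray:
    corr = spec.base_corr.copy()
    idx = {name: i for i, name in enumerate(spec.atlas.names)}
    for a, b, g, delta in spec.edge_deltas:
        if g != group:
            continue
        i, j = idx[a], idx[b]
        corr[i, j] = corr[j, i] = np.clip(corr[i, j] + delta, -0.99, 0.99)
    corr = nearest_positive_definite(corr)
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise SimulationError(f"correlation for group {group!r} not positive definite")
    return corr


def _full_correlation(spec: SimulationSpec, group: str) -> np.ndarray:
    """Motor-block correlation embedded in a (20 + n_extra) latent matrix."""
    motor = _group_correlation(spec, group)
    m, e = spec.atlas.n_nodes, spec.n_extra_rois
    if e == 0:
        return motor
    full = np.full((m + e, m + e), spec.extra_corr)
    full[:m, :m] = motor
    full[:m, m:] = full[m:, :m] = spec.extra_motor_corr
    np.fill_diagonal(full, 1.0)
    return nearest_positive_definite(full)


def simulate_cohort(spec: SimulationSpec) -> CohortTable:
    """Draw a cohort with the specified latent covariance structure.

    Per subject: age ~ Uniform(1, 8) years, sex ~ Bernoulli(0.5), TIV normal
    with group-specific mean; node volumes = atrophy-scaled mean x
    (1 + covariate effects) + noise_sd x latent MVN draw; GMFM/FMFM-type
    scores from the score model on the target node's latent value.
    """
    rng = np.random.default_rng(spec.seed)
    atlas = spec.atlas
    m = atlas.n_nodes
    names = atlas.names
    idx = {name: i for i, name in enumerate(names)}
    target = idx.get(spec.score_model.target_node)

    rows = []
    for group in ("pPVL", "fPVL", "HC"):
        n = spec.group_sizes.get(group, 0)
        if n == 0:
            continue
        age = rng.uniform(1.0, 8.0, n)
        sex = rng.integers(0, 2, n).astype(float)
        tiv_mu, tiv_sd = spec.tiv_by_group.get(group, (1300.0, 150.0))
        tiv = rng.normal(tiv_mu, tiv_sd, n)

        corr = _full_correlation(spec, group)
        latent = rng.multivariate_normal(np.zeros(corr.shape[0]), corr,
                                         size=n, method="cholesky")

        mean = spec.base_mean.copy()
        for node, g, frac in spec.atrophy:
            if g == group:
                mean[idx[node]] *= (1.0 - frac)
        ce = spec.covariate_effects
        covar_scale = (1.0
                       + ce.age * (age - 4.5)[:, None]
                       + ce.sex * (sex - 0.5)[:, None]
                       + ce.tiv * ((tiv - tiv_mu) / tiv_sd)[:, None])
        vols = mean[None, :] * covar_scale + spec.noise_sd[None, :] * latent[:, :m]
        vols = np.clip(vols, 0.0, None)

        extras = None
        if spec.n_extra_rois:
            extras = np.clip(10.0 + 1.0 * latent[:, m:], 0.0, None)

        sm = spec.score_model
        z_target = latent[:, target] if target is not None else np.zeros(n)
        gmfm_total = sm.intercept + sm.slope * z_target + rng.normal(0, sm.noise_sd, n)
        fmfm_total = sm.intercept + 0.5 * sm.slope * z_target + rng.normal(0, sm.noise_sd, n)

        for i in range(n):
            row = {"subject_id": f"{group}_{i + 1:03d}", "group": group,
                   "age": age[i], "sex": sex[i], "TIV": tiv[i]}
            row.update(dict(zip(names, vols[i])))
            if extras is not None:
                row.update({f"xROI{j + 1:03d}": extras[i, j]
                            for j in range(spec.n_extra_rois)})
            row["GMFM_total"] = gmfm_total[i]
            row["FMFM_total"] = fmfm_total[i]
            rows.append(row)

    df = pd.DataFrame(rows)
    extra_cols = [c for c in df.columns if c.startswith("xROI")]
    score_cols = ["GMFM_total", "FMFM_total"]
    return CohortTable(df, atlas, extra_cols, score_cols)


def make_null_cohort(n_per_group: dict[str, int] | int, n_nodes: int = 20,
                     seed: int = 0, n_extra_rois: int = 0) -> CohortTable:
    """Cohort with an identical data-generating process in every group.

    No covariance deltas, no atrophy, no group TIV shift: the exact null for
    type-I-error calibration of the network-based statistic and the metric
    permutation tests.
    """
    if isinstance(n_per_group, int):
        n_per_group = {"pPVL": n_per_group, "HC": n_per_group}
    for g, n in n_per_group.items():
        if n < 4:
            raise ValueError(f"group {g!r} needs >= 4 subjects")
    atlas = generic_atlas(n_nodes)
    spec = SimulationSpec(
        group_sizes=dict(n_per_group), atlas=atlas,
        base_mean=np.full(n_nodes, 10.0),
        edge_deltas=[], atrophy=[],
        tiv_by_group={g: (1300.0, 150.0) for g in ("pPVL", "fPVL", "HC")},
        score_model=ScoreModel(target_node=atlas.names[0]),
        n_extra_rois=n_extra_rois, seed=seed)
    return simulate_cohort(spec)
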