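"""Input/output layer: node atlas, cohort tables, run configuration and ROI
volume extraction from volumetric images.

All downstream matrices (correlation, adjacency, statistics) are ordered by
the :class:`NodeAtlas` node order; this module is the single place that order
is defined.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("motorscn")

GROUPS = ("pPVL", "fPVL", "HC")
COVARIATES = ("age", "sex", "TIV")
REGION_CLASSES = ("cortex", "basal_ganglia_thalamus", "cerebellum")

#: column-name prefixes routed to the motor-score block of a cohort table
SCORE_PREFIXES = ("GMFM", "FMFM", "difficulty_value", "ability_value")
#: global tissue volumes, kept alongside covariates rather than as ROIs
GLOBAL_VOLUME_COLUMNS = ("GM_total", "WM_total")


class CohortSchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


class CohortValidationError(ValueError):
    """The table parses but violates a cohort invariant."""


class GeometryError(ValueError):
    """Two volumetric images do not share a voxel grid / affine."""


# ---------------------------------------------------------------------------
# Node atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Node:
    name: str
    hemisphere: str            # "left" | "right"
    region_class: str          # one of REGION_CLASSES
    atlas_label: int | None = None  # positive integer label in a label map


@dataclass(frozen=True)
class NodeAtlas:
    """Ordered node set shared by every matrix in the pipeline."""

    nodes: tuple[Node, ...]

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        for n in self.nodes:
            if n.region_class not in REGION_CLASSES:
                raise ValueError(f"unknown region_class {n.region_class!r} for {n.name}")
            if n.hemisphere not in ("left", "right"):
                raise ValueError(f"unknown hemisphere {n.hemisphere!r} for {n.name}")
            if n.atlas_label is not None and n.atlas_label <= 0:
                raise ValueError(f"atlas_label must be positive ({n.name})")

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def region_classes(self) -> np.ndarray:
        """Region class per node, in atlas order (the 3-module partition)."""
        return np.array([n.region_class for n in self.nodes])

    def index(self, name: str) -> int:
        return self.names.index(name)


#: (abbreviation, region class) for the ten homotopic motor regions:
#: precentral gyrus, supplementary motor area, postcentral gyrus, superior
#: parietal lobule, paracentral lobule, caudate, putamen, pallidum, thalamus
#: and cerebellar hemisphere.
_MOTOR_REGIONS = (
    ("PrG", "cortex"),
    ("SMA", "cortex"),
    ("PoG", "cortex"),
    ("SPL", "cortex"),
    ("PaL", "cortex"),
    ("Cau", "basal_ganglia_thalamus"),
    ("Put", "basal_ganglia_thalamus"),
    ("Pal", "basal_ganglia_thalamus"),
    ("Tha", "basal_ganglia_thalamus"),
    ("Cer", "cerebellum"),
)


def motor_atlas() -> NodeAtlas:
    """The default 20-node motor atlas: ten homotopic left/right pairs."""
    nodes = []
    label = 1
    for abbr, cls in _MOTOR_REGIONS:
        for side, prefix in (("left", "L"), ("right", "R")):
            nodes.append(Node(name=f"{prefix}{abbr}", hemisphere=side,
                              region_class=cls, atlas_label=label))
            label += 1
    return NodeAtlas(nodes=tuple(nodes))


def generic_atlas(n_nodes: int) -> NodeAtlas:
    """An unnamed atlas of ``n_nodes`` nodes (for simulation harnesses)."""
    if n_nodes == 20:
        return motor_atlas()
    classes = REGION_CLASSES
    nodes = tuple(
        Node(name=f"N{i + 1:02d}", hemisphere=("left" if i % 2 == 0 else "right"),
             region_class=classes[i % len(classes)], atlas_label=i + 1)
        for i in range(n_nodes)
    )
    return NodeAtlas(nodes=nodes)


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Per-subject ROI volumes, covariates, group labels and motor scores.

    ``data`` holds one row per subject.  Node volume columns are stored in
    atlas order.  Extra (non-atlas) ROI columns support the whole-brain
    specificity test; score columns are recognised by name prefix.
    """

    data: pd.DataFrame
    atlas: NodeAtlas
    extra_nodes: list[str] = field(default_factory=list)
    score_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def volumes(self, include_extras: bool = False) -> pd.DataFrame:
        cols = self.atlas.names + (self.extra_nodes if include_extras else [])
        return self.data[cols]

    def covariates(self) -> pd.DataFrame:
        return self.data[list(COVARIATES)]

    def group_counts(self) -> dict[str, int]:
        return self.data["group"].value_counts().to_dict()

    def subset(self, groups: Sequence[str]) -> "CohortTable":
        sub = self.data[self.data["group"].isin(list(groups))].reset_index(drop=True)
        return CohortTable(sub, self.atlas, list(self.extra_nodes),
                           list(self.score_columns))

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        required = ["subject_id", "group", *COVARIATES]
        for col in required:
            if col not in df.columns:
                raise CohortSchemaError(f"missing required column {col!r}")
        for name in self.atlas.names:
            if name not in df.columns:
                raise CohortSchemaError(f"missing volume column {name!r}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise CohortValidationError(f"duplicated subject_id {dup!r}")
        bad = set(df["group"].unique()) - set(GROUPS)
        if bad:
            raise CohortValidationError(f"unknown group label(s) {sorted(bad)!r}")
        vols = df[self.atlas.names + self.extra_nodes].to_numpy(dtype=float)
        if not np.isfinite(vols).all():
            raise CohortValidationError("non-finite volume values present")
        if (vols < 0).any():
            raise CohortValidationError("negative volume values present")
        cov = df[list(COVARIATES)].to_numpy(dtype=float)
        if not np.isfinite(cov).all():
            raise CohortValidationError("missing/non-finite covariate values")


def _coerce_sex(series: pd.Series) -> pd.Series:
    """Map a two-level sex column to {0, 1}.

    Numeric 0/1 is passed through; any two-level string pair is mapped
    alphabetically (first level -> 0) and the mapping is logged.  Convention:
    male=1, female=0 when the labels are the English words.
    """
    if pd.api.types.is_numeric_dtype(series):
        vals = set(pd.unique(series.dropna()))
        if not vals <= {0, 1, 0.0, 1.0}:
            raise CohortValidationError(f"numeric sex column must be 0/1, got {sorted(vals)}")
        return series.astype(float)
    levels = sorted(pd.unique(series.dropna().astype(str)))
    if len(levels) > 2:
        raise CohortValidationError(f"sex column has more than two levels: {levels}")
    lower = [s.lower() for s in levels]
    if set(lower) <= {"m", "male", "f", "female"}:
        mapping = {lev: (1.0 if lev.lower() in ("m", "male") else 0.0) for lev in levels}
    else:
        mapping = {lev: float(i) for i, lev in enumerate(levels)}
    logger.info("sex column mapped: %s", mapping)
    return series.astype(str).map(mapping)


def read_cohort(path: str | Path, atlas: NodeAtlas | None = None) -> CohortTable:
    """Read a cohort CSV/TSV (delimiter auto-detected) and validate it.

    Required columns: subject_id, group, age, sex, TIV and one column per
    atlas node.  Remaining columns are routed by name: score prefixes
    (GMFM*/FMFM*/difficulty_value/ability_value) to scores, GM_total/WM_total
    kept as global volumes, everything else to extra ROI volumes.
    """
    atlas = atlas or motor_atlas()
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("subject_id", "group", *COVARIATES):
        if col not in df.columns:
            raise CohortSchemaError(f"missing required column {col!r}")
    for name in atlas.names:
        if name not in df.columns:
            raise CohortSchemaError(f"missing volume column {name!r}")
    df["subject_id"] = df["subject_id"].astype(str)
    df["sex"] = _coerce_sex(df["sex"])

    known = {"subject_id", "group", *COVARIATES, *atlas.names}
    score_cols, extra_cols = [], []
    for col in df.columns:
        if col in known or col in GLOBAL_VOLUME_COLUMNS:
            continue
        if any(col.startswith(p) for p in SCORE_PREFIXES):
            score_cols.append(col)
        else:
            extra_cols.append(col)

    numeric_cols = [*COVARIATES, *atlas.names, *extra_cols,
                    *[c for c in GLOBAL_VOLUME_COLUMNS if c in df.columns]]
    for col in numeric_cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise CohortSchemaError(
                f"non-numeric value in column {col!r}, row {row}") from exc

    # normalise column order: ids/covariates, atlas order, extras, scores
    ordered = (["subject_id", "group", *COVARIATES]
               + [c for c in GLOBAL_VOLUME_COLUMNS if c in df.columns]
               + atlas.names + extra_cols + score_cols)
    df = df[ordered]
    return CohortTable(df, atlas, extra_cols, score_cols)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort table to CSV at full float precision (round-trip safe)."""
    cohort.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis parameters with the study defaults.

    Density grid 0.10-0.50 in steps of 0.01 (41 levels); 1000 permutations
    for metric comparisons; 5000 for the network-based statistic; 5000 random
    node subsets for the specificity test; edge-statistic threshold 3.1 and
    family-wise alpha 0.05; hubs at 1 SD above the mean degree.
    """

    density_min: float = 0.10
    density_max: float = 0.50
    density_step: float = 0.01
    n_perm_metrics: int = 1000
    n_perm_nbs: int = 5000
    n_random_sets: int = 5000
    nbs_stat_threshold: float = 3.1
    fwe_alpha: float = 0.05
    hub_sd_multiplier: float = 1.0
    n_null_graphs: int = 100
    rng_seed: int = 0
    residual_scope: str = "pooled"      # "pooled" | "per-group"
    edge_ranking: str = "signed"        # "signed" | "absolute"
    hub_rule: str = "degree"            # "degree" | "participation"
    specificity_pool: str = "exclude_motor"  # or "include_motor"

    def __post_init__(self) -> None:
        if not (0 < self.density_min <= self.density_max < 1):
            raise ValueError("require 0 < density_min <= density_max < 1")
        if self.density_step <= 0:
            raise ValueError("density_step must be > 0")
        for name in ("n_perm_metrics", "n_perm_nbs", "n_random_sets", "n_null_graphs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nbs_stat_threshold <= 0 or not (0 < self.fwe_alpha < 1):
            raise ValueError("thresholds must be positive; 0 < fwe_alpha < 1")
        if self.residual_scope not in ("pooled", "per-group"):
            raise ValueError("residual_scope must be 'pooled' or 'per-group'")
        if self.edge_ranking not in ("signed", "absolute"):
            raise ValueError("edge_ranking must be 'signed' or 'absolute'")

    @property
    def density_grid(self) -> np.ndarray:
        n = int(round((self.density_max - self.density_min) / self.density_step)) + 1
        return np.round(self.density_min + self.density_step * np.arange(n), 10)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON (YAML is a superset, so one loader)."""
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        valid = {f.name for f in fields(cls)}
        unknown = set(payload) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self) -> str:
        return json.dumps({f.name: getattr(self, f.name) for f in fields(self)},
                          indent=2)

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# ROI volume extraction from volumetric images
# ---------------------------------------------------------------------------

def extract_roi_volumes(prob_img, label_img, atlas: NodeAtlas) -> dict[str, float]:
    """Tissue volume (ml) per atlas node from a probability map + label map.

    For a node with atlas label L the volume is the sum of the tissue
    probability over voxels labelled L, times the voxel volume in mm^3,
    divided by 1000 (mm^3 -> ml).  Nodes without an atlas label are omitted;
    labels absent from the label map yield volume 0 with a warning.

    Both images must share shape and affine (element-wise within 1e-4).
    """
    import nibabel as nib  # local import: volumetric I/O is optional at runtime

    if isinstance(prob_img, (str, Path)):
        prob_img = nib.load(str(prob_img))
    if isinstance(label_img, (str, Path)):
        label_img = nib.load(str(label_img))

    if prob_img.shape != label_img.shape:
        raise GeometryError(
            f"shape mismatch: {prob_img.shape} vs {label_img.shape}")
    if not np.allclose(prob_img.affine, label_img.affine, atol=1e-4):
        raise GeometryError("affine mismatch between probability and label map")

    prob = np.asarray(prob_img.dataobj, dtype=float)
    labels = np.asarray(label_img.dataobj)
    if not np.allclose(labels, np.round(labels)):
        raise ValueError("label map is not integer-valued")
    labels = np.round(labels).astype(int)
    if prob.min() < -1e-9 or prob.max() > 1 + 1e-9:
        raise ValueError("probability map values must lie in [0, 1]")

    voxel_volume_mm3 = float(abs(np.linalg.det(prob_img.affine[:3, :3])))
    out: dict[str, float] = {}
    for node in atlas.nodes:
        if node.atlas_label is None:
            continue
        mask = labels == node.atlas_label
        if not mask.any():
            logger.warning("label %d (%s) absent from label map; volume set to 0",
                           node.atlas_label, node.name)
            out[node.name] = 0.0
        else:
            out[node.name] = float(prob[mask].sum() * voxel_volume_mm3 / 1000.0)
    return out
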