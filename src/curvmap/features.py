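"""Curvature-weighted surface features (HCM/ECM) and the molecule × feature
table.

A feature is the region sum of a physico-chemical channel weighted by a
geometric penalty evaluated on patch-averaged curvature,

    F = ⟨ Σ_A φ · P(s̄, c̄ at cut-off) ⟩_frames,

aggregated over trajectory frames by one of MIN/MAX/AVG/VAR.  The penalties
encode three protein-protein interaction regimes:

    P1 = (s+1)/2 · c        — exposed, highly curved protrusions
    P2 = (s+1)/2 · e^(−c)   — flat-but-outward complementary patches
    P3 = erf(s · c)         — sigmoidal protrusion preference with plateau

The default combinatorial grid — 3 properties × 2 signatures × 3 penalties ×
3 cut-offs × 4 statistics × 8 regions = 1728 columns — is the full
descriptor family; column names follow the grammar
``"HCM (logP) +, P3, 10 Å, AVG, CDRH1"``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .curvature import (
    DEFAULT_CUTOFFS,
    CurvatureField,
    PatchField,
    patch_average,
    principal_curvatures,
)
from .errors import ConsistencyError, ParameterError
from .properties import (
    ElectrostaticModel,
    SurfaceProperty,
    electrostatic_potential,
    mlp_project,
)
from .structures import (
    HydrophobicityScale,
    RegionAnnotation,
    Structure,
    Trajectory,
    atom_class,
    load_scale,
)
from .surfaces import SurfaceMesh, build_surface

logger = logging.getLogger(__name__)

PENALTY_KINDS = ("P1", "P2", "P3")
PROPERTIES = ("HCM (ww)", "HCM (logP)", "ECM")
SIGNATURES = ("+", "-")
STATISTICS = ("MIN", "MAX", "AVG", "VAR")
REGIONS = ("Fv", "CDR", "CDRH1", "CDRH2", "CDRH3", "CDRL1", "CDRL2", "CDRL3")


def penalty(s, c, kind: str):
    """Evaluate a penalty function on (shape index, curvedness) arrays."""
    s = np.asarray(s, dtype=float)
    c = np.asarray(c, dtype=float)
    if kind == "P1":
        out = 0.5 * (s + 1.0) * c
    elif kind == "P2":
        out = 0.5 * (s + 1.0) * np.exp(-c)
    elif kind == "P3":
        out = erf(s * c)
    else:
        raise ParameterError(f"unknown penalty kind {kind!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FeatureSpec:
    """One cell of the combinatorial descriptor grid."""

    property_id: str
    signature: str
    penalty: str
    cutoff: float
    statistic: str
    region: str

    def __post_init__(self) -> None:
        if self.property_id not in PROPERTIES:
            raise ParameterError(f"unknown property {self.property_id!r}")
        if self.signature not in SIGNATURES:
            raise ParameterError(f"signature must be '+' or '-'")
        if self.penalty not in PENALTY_KINDS:
            raise ParameterError(f"unknown penalty {self.penalty!r}")
        if self.statistic not in STATISTICS:
            raise ParameterError(f"unknown statistic {self.statistic!r}")
        if self.region not in REGIONS:
            raise ParameterError(f"unknown region {self.region!r}")

    @property
    def name(self) -> str:
        return (
            f"{self.property_id} {self.signature}, {self.penalty}, "
            f"{self.cutoff:g} Å, {self.statistic}, {self.region}"
        )

    @classmethod
    def from_name(cls, name: str) -> "FeatureSpec":
        head, pen, cut, stat, region = [p.strip() for p in name.split(",")]
        prop, sig = head.rsplit(" ", 1)
        return cls(
            property_id=prop,
            signature=sig,
            penalty=pen,
            cutoff=float(cut.split()[0]),
            statistic=stat,
            region=region,
        )


def default_grid(
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> list[FeatureSpec]:
    """The full 3×2×3×3×4×8 = 1728-column descriptor grid, in stable order."""
    return [
        FeatureSpec(prop, sig, pen, float(cut), stat, region)
        for prop, sig, pen, cut, stat, region in itertools.product(
            PROPERTIES, SIGNATURES, PENALTY_KINDS, cutoffs, STATISTICS, REGIONS
        )
    ]


def trajectory_statistic(values: Sequence[float], statistic: str) -> float:
    """MIN/MAX/AVG over frames; VAR is the population variance (ddof=0)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("empty per-frame series")
    if statistic == "MIN":
        return float(v.min())
    if statistic == "MAX":
        return float(v.max())
    if statistic == "AVG":
        return float(v.mean())
    if statistic == "VAR":
        return float(v.var(ddof=0))
    raise ParameterError(f"unknown statistic {statistic!r}")


def frame_feature(
    channel_values: np.ndarray,
    patch: PatchField,
    region_mask: np.ndarray,
    penalty_kind: str,
    area_weights: np.ndarray | None = None,
) -> float:
    """Σ over masked points of φ_channel · P(s̄, c̄); empty region → 0.

    ``area_weights`` switches to the area-weighted sum Σ φ·P·dA.  Points
    flagged invalid in the patch field are excluded.
    """
    channel_values = np.asarray(channel_values, dtype=float)
    if len(channel_values) != len(patch.s_bar):
        raise ConsistencyError("channel length != patch-field length")
    mask = np.asarray(region_mask, dtype=bool) & patch.valid
    if not mask.any():
        return 0.0
    p = penalty(patch.s_bar[mask], patch.c_bar[mask], penalty_kind)
    contrib = channel_values[mask] * p
    if area_weights is not None:
        contrib = contrib * area_weights[mask]
    return float(contrib.sum())


# ---------------------------------------------------------------------------
# Per-frame field computation
# ---------------------------------------------------------------------------


@dataclass
class FeatureConfig:
    """Knobs of the feature pipeline, recorded in table provenance."""

    probe_radius: float = 1.4  # Å
    grid_spacing: float = 0.6  # Å, native-mesher resolution
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    stride: int = 1  # frame subsampling
    area_weighted: bool = False
    electrostatics: ElectrostaticModel = dc_field(default_factory=ElectrostaticModel)
    hydrophobicity_mode: str = "scales"  # "scales" | "stored"
    mesher: Callable[..., SurfaceMesh] | None = None  # hook: Structure -> SurfaceMesh

    def as_provenance(self) -> dict:
        return {
            "probe_radius": self.probe_radius,
            "grid_spacing": self.grid_spacing,
            "cutoffs": list(self.cutoffs),
            "stride": self.stride,
            "area_weighted": self.area_weighted,
            "electrostatic_mode": self.electrostatics.mode,
            "hydrophobicity_mode": self.hydrophobicity_mode,
        }


def hydrophobicity_vector(structure: Structure, scale: HydrophobicityScale) -> np.ndarray:
    """Per-atom normalized hydrophobicities under a scale, without mutating
    the structure (unknown keys fall back to 0 with a log note)."""
    out = np.zeros(len(structure))
    for i, a in enumerate(structure.atoms):
        key = (
            a.residue_name
            if scale.granularity == "per-residue"
            else atom_class(a.residue_name, a.name, a.element)
        )
        if key in scale:
            out[i] = scale.normalized(key)
        else:
            logger.debug("scale %s: no value for %r; using 0", scale.scale_id, key)
    return out


@dataclass
class FrameFields:
    """Everything the feature sums need for one frame."""

    mesh: SurfaceMesh
    curvature: CurvatureField
    patches: dict[float, PatchField]
    properties: dict[str, SurfaceProperty]
    region_masks: dict[str, np.ndarray]


def region_point_masks(
    mesh: SurfaceMesh, structure: Structure, annotation: RegionAnnotation
) -> dict[str, np.ndarray]:
    """Boolean point masks per region: a point belongs to a region when its
    nearest atom's residue carries the label."""
    residue_ids = structure.residue_ids
    masks = {region: np.zeros(len(mesh), dtype=bool) for region in REGIONS}
    for pt, atom_idx in enumerate(mesh.nearest_atom):
        if atom_idx < 0:
            continue
        for label in annotation.labels_for(residue_ids[atom_idx]):
            masks[label][pt] = True
    return masks


def compute_frame_fields(
    structure: Structure,
    annotation: RegionAnnotation,
    config: FeatureConfig | None = None,
    scales: Mapping[str, HydrophobicityScale] | None = None,
) -> FrameFields:
    """Mesh, curvature patches, property channels and region masks for one frame.

    Structures read straight from PDB lack radii/charges; those are assigned
    from the packaged default tables on the fly.
    """
    config = FeatureConfig() if config is None else config
    radii = structure.radii
    if not (np.all(np.isfinite(radii)) and np.all(radii > 0)):
        from .structures import assign_parameters

        structure = assign_parameters(structure)
    mesher = config.mesher or (
        lambda s: build_surface(
            s, probe_radius=config.probe_radius, grid_spacing=config.grid_spacing
        )
    )
    mesh = mesher(structure)
    curv = principal_curvatures(mesh)
    patches = {
        cutoff: patch_average(curv, mesh, cutoff, area_weighted=False)
        for cutoff in config.cutoffs
    }
    if config.hydrophobicity_mode == "stored":
        f = structure.hydrophobicities
        hcm_inputs = {"HCM (ww)": f, "HCM (logP)": f}
    else:
        if scales is None:
            scales = {"ww": load_scale("ww"), "logP": load_scale("logP")}
        hcm_inputs = {
            "HCM (ww)": hydrophobicity_vector(structure, scales["ww"]),
            "HCM (logP)": hydrophobicity_vector(structure, scales["logP"]),
        }
    props = {
        pid: mlp_project(structure, mesh, hydrophobicities=f, property_id=pid)
        for pid, f in hcm_inputs.items()
    }
    props["ECM"] = electrostatic_potential(structure, mesh, config.electrostatics)
    masks = region_point_masks(mesh, structure, annotation)
    return FrameFields(
        mesh=mesh, curvature=curv, patches=patches, properties=props, region_masks=masks
    )


# ---------------------------------------------------------------------------
# The molecule × feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Molecule × feature matrix with provenance metadata."""

    table: pd.DataFrame  # index: molecule ids; columns: FeatureSpec names
    specs: list[FeatureSpec]
    provenance: dict = dc_field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="molecule_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="molecule_id")
        specs = []
        for col in df.columns:
            try:
                specs.append(FeatureSpec.from_name(col))
            except (ValueError, ParameterError):
                pass  # auxiliary columns are allowed
        return cls(table=df, specs=specs, provenance={"source": str(path)})


def _frame_values(
    fields: FrameFields,
    combos: list[tuple[str, str, str, float, str]],
    area_weighted: bool,
) -> dict[tuple, float]:
    """Evaluate Σ_A φ·P for every (property, signature, penalty, cutoff,
    region) combination on one frame."""
    out = {}
    area = fields.mesh.area_weights if area_weighted else None
    # cache per-point penalty vectors: they do not depend on property/region
    pen_cache: dict[tuple[str, float], np.ndarray] = {}
    for prop, sig, pen, cut, region in combos:
        key = (pen, cut)
        patch = fields.patches[cut]
        if key not in pen_cache:
            pen_cache[key] = penalty(patch.s_bar, patch.c_bar, pen)
        channel = fields.properties[prop].channel(sig)
        mask = fields.region_masks[region] & patch.valid
        if not mask.any():
            out[(prop, sig, pen, cut, region)] = 0.0
            continue
        contrib = channel[mask] * pen_cache[key][mask]
        if area is not None:
            contrib = contrib * area[mask]
        out[(prop, sig, pen, cut, region)] = float(contrib.sum())
    return out


def build_feature_table(
    trajectories: Mapping[str, Trajectory],
    annotations: Mapping[str, RegionAnnotation] | RegionAnnotation,
    specs: Sequence[FeatureSpec] | None = None,
    config: FeatureConfig | None = None,
) -> FeatureTable:
    """Evaluate the descriptor grid for every molecule.

    ``annotations`` may be shared (one annotation applied to every molecule)
    or a per-molecule mapping.  Frames are subsampled by ``config.stride``.
    Molecules whose evaluation fails are skipped with an error entry in the
    provenance rather than aborting the run.
    """
    config = FeatureConfig() if config is None else config
    specs = default_grid(config.cutoffs) if specs is None else list(specs)
    combos = sorted(
        {(sp.property_id, sp.signature, sp.penalty, sp.cutoff, sp.region) for sp in specs}
    )
    rows = {}
    errors = {}
    for mol_id, traj in trajectories.items():
        annot = (
            annotations[mol_id]
            if isinstance(annotations, Mapping)
            else annotations
        )
        try:
            frame_series: dict[tuple, list[float]] = {c: [] for c in combos}
            for frame in traj.frames[:: config.stride]:
                fields = compute_frame_fields(frame, annot, config)
                vals = _frame_values(fields, combos, config.area_weighted)
                for c in combos:
                    frame_series[c].append(vals[c])
            row = {
                sp.name: trajectory_statistic(
                    frame_series[
                        (sp.property_id, sp.signature, sp.penalty, sp.cutoff, sp.region)
                    ],
                    sp.statistic,
                )
                for sp in specs
            }
            rows[mol_id] = row
        except Exception as exc:  # noqa: BLE001 - isolate per-molecule failures
            logger.error("molecule %s failed: %s", mol_id, exc)
            errors[mol_id] = str(exc)
    if not rows:
        raise ParameterError("no molecule could be evaluated")
    table = pd.DataFrame.from_dict(rows, orient="index")[[sp.name for sp in specs]]
    return FeatureTable(
        table=table,
        specs=specs,
        provenance={**config.as_provenance(), "errors": errors},
    )
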