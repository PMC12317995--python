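"""Synthetic inputs for every stage of the pipeline.

Three fixture families, all pure functions of their parameters/seeds:

* analytic surfaces (sphere, plane, cylinder, saddle, torus) meshed with
  exact normals and paired with closed-form principal curvatures — the
  ground truth the curvature estimator is judged against;
* toy atom clusters ("proteins") with globule / protrusion / cavity motifs
  and Gaussian-jitter trajectories, exercising the surface, projection and
  feature machinery without real chemistry;
* molecule × feature study tables with a planted 3-feature linear signal
  plus noise, standing in for an experimental aggregation-rate dataset.

Closed-form curvature uses the package-wide orientation: outward normals,
convex protrusions positive.  For a parametric surface with second
fundamental form L, M, N relative to the outward normal, the package's
principal curvatures are the negated eigenvalues of the shape operator
(so a sphere of radius R has κ₁ = κ₂ = +1/R).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curvature import CurvatureField
from .errors import ParameterError
from .features import default_grid
from .regression import StudyDataset
from .structures import (
    AtomRecord,
    RegionAnnotation,
    Structure,
    Trajectory,
    annotate_regions,
    load_scale,
)
from .surfaces import SurfaceMesh

# ---------------------------------------------------------------------------
# Analytic meshes with closed-form curvature
# ---------------------------------------------------------------------------


def _truth_field(kappa1: np.ndarray, kappa2: np.ndarray) -> CurvatureField:
    # independent closed forms for s and c (kept inline on purpose)
    k1, k2 = np.asarray(kappa1, float), np.asarray(kappa2, float)
    num, den = k1 + k2, k1 - k2
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (2.0 / np.pi) * np.arctan(num / den)
    s = np.where(den == 0.0, np.sign(num), s)
    c = np.sqrt(0.5 * (k1 * k1 + k2 * k2))
    return CurvatureField(
        kappa1=k1, kappa2=k2, s=s, c=c, valid=np.ones(len(k1), dtype=bool)
    )


def _grid_triangles(nu: int, nv: int, wrap_u: bool = False, wrap_v: bool = False) -> np.ndarray:
    tris = []
    ulim = nu if wrap_u else nu - 1
    vlim = nv if wrap_v else nv - 1
    for i in range(ulim):
        for j in range(vlim):
            i1 = (i + 1) % nu
            j1 = (j + 1) % nv
            a, b = i * nv + j, i1 * nv + j
            c, d = i1 * nv + j1, i * nv + j1
            tris.append((a, b, c))
            tris.append((a, c, d))
    return np.asarray(tris, dtype=int)


def _mesh(positions, normals, triangles, kappa1, kappa2, kind: str):
    mesh = SurfaceMesh(
        positions=np.asarray(positions, float),
        normals=np.asarray(normals, float),
        triangles=triangles,
        nearest_atom=np.full(len(positions), -1, dtype=int),
        provenance={"source": "analytic", "shape": kind},
    )
    return mesh, _truth_field(np.asarray(kappa1, float), np.asarray(kappa2, float))


def sphere_mesh(radius: float = 10.0, subdivisions: int = 3):
    """Icosphere of exact radius; truth κ₁ = κ₂ = 1/R everywhere."""
    import trimesh

    if radius <= 0:
        raise ParameterError("radius must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    verts = np.asarray(ico.vertices, float)
    verts *= radius / np.linalg.norm(verts, axis=1, keepdims=True)
    normals = verts / radius
    n = len(verts)
    k = np.full(n, 1.0 / radius)
    return _mesh(verts, normals, np.asarray(ico.faces, int), k, k, "sphere")


def plane_mesh(extent: float = 10.0, n: int = 21):
    """Flat square patch; truth κ₁ = κ₂ = 0 (s = 0 by convention)."""
    xs = np.linspace(-extent / 2, extent / 2, n)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n * n)])
    normals = np.tile([0.0, 0.0, 1.0], (n * n, 1))
    zero = np.zeros(n * n)
    return _mesh(verts, normals, _grid_triangles(n, n), zero, zero, "plane")


def cylinder_mesh(radius: float = 10.0, height: float = 20.0, n_theta: int = 48, n_z: int = 21):
    """Open tube; truth κ₁ = 1/R, κ₂ = 0 with outward radial normals."""
    if radius <= 0:
        raise ParameterError("radius must be positive")
    thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(-height / 2, height / 2, n_z)
    tt, zz = np.meshgrid(thetas, zs, indexing="ij")
    verts = np.column_stack(
        [radius * np.cos(tt).ravel(), radius * np.sin(tt).ravel(), zz.ravel()]
    )
    normals = np.column_stack(
        [np.cos(tt).ravel(), np.sin(tt).ravel(), np.zeros(tt.size)]
    )
    k1 = np.full(tt.size, 1.0 / radius)
    k2 = np.zeros(tt.size)
    return _mesh(verts, normals, _grid_triangles(n_theta, n_z, wrap_u=True), k1, k2, "cylinder")


def saddle_mesh(a: float = 1.0, b: float = 1.0, extent: float = 1.0, n: int = 25):
    """Graph z = (a·x² − b·y²)/2 with upward normals.

    Closed-form curvatures from the graph-surface fundamental forms,
    negated into the package orientation (at the origin: κ = ±a, ±b).
    """
    xs = np.linspace(-extent / 2, extent / 2, n)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    x, y = gx.ravel(), gy.ravel()
    z = 0.5 * (a * x * x - b * y * y)
    fx, fy = a * x, -b * y
    fxx, fyy, fxy = a, -b, 0.0
    w = np.sqrt(1.0 + fx * fx + fy * fy)
    normals = np.column_stack([-fx / w, -fy / w, 1.0 / w])
    verts = np.column_stack([x, y, z])

    E, F, G = 1 + fx * fx, fx * fy, 1 + fy * fy
    L, M, N = fxx / w, fxy / w, fyy / w
    # eigenvalues of the shape operator I⁻¹·II, then negate (orientation)
    det_i = E * G - F * F
    m11 = (G * L - F * M) / det_i
    m12 = (G * M - F * N) / det_i
    m21 = (E * M - F * L) / det_i
    m22 = (E * N - F * M) / det_i
    tr, det = m11 + m22, m11 * m22 - m12 * m21
    disc = np.sqrt(np.maximum(tr * tr / 4 - det, 0.0))
    e1, e2 = tr / 2 + disc, tr / 2 - disc
    k1, k2 = -e2, -e1  # negate and restore κ₁ ≥ κ₂
    return _mesh(verts, normals, _grid_triangles(n, n), k1, k2, "saddle")


def torus_mesh(R: float = 10.0, r: float = 3.0, n_u: int = 64, n_v: int = 32):
    """Torus with outward normals; truth κ_tube = 1/r, κ_ring = cos v/(R + r·cos v)."""
    if R <= 0 or r <= 0 or r >= R:
        raise ParameterError("need 0 < r < R")
    us = np.linspace(0, 2 * np.pi, n_u, endpoint=False)
    vs = np.linspace(0, 2 * np.pi, n_v, endpoint=False)
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    cu, su, cv, sv = np.cos(uu), np.sin(uu), np.cos(vv), np.sin(vv)
    ring = R + r * cv
    verts = np.column_stack([(ring * cu).ravel(), (ring * su).ravel(), (r * sv).ravel()])
    normals = np.column_stack([(cv * cu).ravel(), (cv * su).ravel(), sv.ravel()])
    k_tube = np.full(uu.size, 1.0 / r)
    k_ring = (cv / ring).ravel()
    k1 = np.maximum(k_tube, k_ring)
    k2 = np.minimum(k_tube, k_ring)
    return _mesh(verts, normals, _grid_triangles(n_u, n_v, wrap_u=True, wrap_v=True), k1, k2, "torus")


_SHAPES = {
    "sphere": sphere_mesh,
    "plane": plane_mesh,
    "cylinder": cylinder_mesh,
    "saddle": saddle_mesh,
    "torus": torus_mesh,
}


def make_analytic_mesh(kind: str, **params):
    """Dispatch to a shape constructor; returns (mesh, ground-truth field)."""
    if kind not in _SHAPES:
        raise ParameterError(f"unknown shape {kind!r}; choose from {sorted(_SHAPES)}")
    return _SHAPES[kind](**params)


# ---------------------------------------------------------------------------
# Toy proteins
# ---------------------------------------------------------------------------

_TOY_RESIDUES = ("ALA", "LEU", "ARG", "ASP", "GLY", "SER")
_TOY_CHARGES = {"ARG": 0.5, "ASP": -0.5}


@dataclass
class ToyProtein:
    """A generated atom cluster plus bookkeeping for its motif."""

    structure: Structure
    motif: str
    motif_atom_ids: list[int] = field(default_factory=list)  # stalk/pocket-rim atoms
    pocket_center: np.ndarray | None = None


def make_toy_protein(
    n_atoms: int = 30,
    motif: str = "globule",
    seed: int = 0,
    spacing: float = 2.0,
    jitter: float = 0.3,
) -> ToyProtein:
    """Seeded atom packing with an optional protrusion or cavity motif.

    Atoms sit on a jittered cubic lattice inside a ball (carbon radii,
    single-atom residues cycling a handful of amino-acid names, two chains
    H/L).  ``protrusion`` adds a 3-atom stalk along +z (a high-s̄ patch at
    its tip); ``cavity`` adds a ring of rim atoms around an empty crater on
    top (a negative-s̄ pocket at its center).  Hydrophobicities are the
    residue-scale values; ARG/ASP carry coarse charges.
    """
    if n_atoms < 1:
        raise ParameterError("n_atoms must be >= 1")
    if motif not in ("globule", "protrusion", "cavity"):
        raise ParameterError(f"unknown motif {motif!r}")
    rng = np.random.default_rng(seed)
    m = int(np.ceil((n_atoms ** (1 / 3)))) + 2
    axis = spacing * (np.arange(-m, m + 1))
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    lattice = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    lattice = lattice[np.argsort(np.linalg.norm(lattice, axis=1), kind="stable")]
    coords = lattice[:n_atoms] + rng.normal(0.0, jitter, size=(n_atoms, 3))

    motif_ids: list[int] = []
    pocket_center = None
    z_top = coords[:, 2].max()
    if motif == "protrusion":
        stalk = np.array(
            [[0.0, 0.0, z_top + (k + 1) * spacing] for k in range(3)]
        )
        motif_ids = list(range(n_atoms, n_atoms + 3))
        coords = np.vstack([coords, stalk])
    elif motif == "cavity":
        ring_r = 3.5
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        rim = np.column_stack(
            [ring_r * np.cos(angles), ring_r * np.sin(angles),
             np.full(8, z_top + 0.8 * spacing)]
        )
        motif_ids = list(range(n_atoms, n_atoms + 8))
        pocket_center = np.array([0.0, 0.0, z_top + 0.8 * spacing])
        coords = np.vstack([coords, rim])

    ww = load_scale("ww")
    atoms = []
    n_total = len(coords)
    half = (n_total + 1) // 2
    for i, xyz in enumerate(coords):
        resname = _TOY_RESIDUES[i % len(_TOY_RESIDUES)]
        chain = "H" if i < half else "L"
        resnum = i + 1 if i < half else i - half + 1
        atoms.append(
            AtomRecord(
                atom_id=i + 1,
                element="C",
                name="CA",
                coords=xyz,
                residue_id=(chain, resnum, ""),
                residue_name=resname,
                radius=1.7,
                partial_charge=_TOY_CHARGES.get(resname, 0.0),
                hydrophobicity=ww.normalized(resname),
            )
        )
    return ToyProtein(
        structure=Structure(atoms=atoms),
        motif=motif,
        motif_atom_ids=motif_ids,
        pocket_center=pocket_center,
    )


def make_jittered_trajectory(
    structure: Structure, n_frames: int, sd: float = 0.3, seed: int = 0
) -> Trajectory:
    """Frame 0 is the input structure; later frames add isotropic Gaussian
    coordinate noise (a crude stand-in for thermal fluctuation)."""
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames = [Structure(atoms=list(structure.atoms), frame_index=0)]
    for k in range(1, n_frames):
        noise = rng.normal(0.0, sd, size=(len(structure), 3))
        atoms = []
        for a, dx in zip(structure.atoms, noise):
            atoms.append(
                AtomRecord(
                    atom_id=a.atom_id,
                    element=a.element,
                    name=a.name,
                    coords=a.coords + dx,
                    residue_id=a.residue_id,
                    residue_name=a.residue_name,
                    radius=a.radius,
                    partial_charge=a.partial_charge,
                    hydrophobicity=a.hydrophobicity,
                )
            )
        frames.append(Structure(atoms=atoms, frame_index=k))
    return Trajectory(frames=frames, time_step_label=f"jitter(sd={sd})")


def toy_region_definitions(structure: Structure) -> list[tuple[str, str, int, int]]:
    """Region ranges covering a toy protein: Fv spans each chain; three CDR
    windows are carved out of each chain's residue range."""
    defs = []
    for chain in sorted(structure.chains()):
        nums = sorted({rid[1] for rid in structure.residue_ids if rid[0] == chain})
        lo, hi = nums[0], nums[-1]
        defs.append(("Fv", chain, lo, hi))
        span = max(hi - lo + 1, 1)
        third = max(span // 3, 1)
        prefix = "CDRH" if chain == "H" else "CDRL"
        for k in range(3):
            start = lo + k * third
            end = min(lo + (k + 1) * third - 1, hi)
            if start <= end:
                defs.append((f"{prefix}{k + 1}", chain, start, end))
    return defs


def toy_annotation(structure: Structure) -> RegionAnnotation:
    return annotate_regions(structure, toy_region_definitions(structure))


# ---------------------------------------------------------------------------
# Planted-signal study tables
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """A molecule × feature table with a known 3-feature linear signal."""

    X: pd.DataFrame
    y: np.ndarray
    planted_columns: tuple[str, str, str]
    coefficients: tuple[float, float, float]
    noise_sd: float
    seed: int

    @property
    def dataset(self) -> StudyDataset:
        return StudyDataset(X=self.X, y=self.y)


def make_synthetic_study(
    n_molecules: int = 20,
    n_features: int = 40,
    noise_sd: float | None = None,
    seed: int = 0,
    planted_rho: float = 0.5,
    coefficients: tuple[float, float, float] = (1.0, 0.9, 0.8),
) -> SyntheticStudy:
    """Generate (X, y) with y linear in three planted columns plus noise.

    The three planted columns share a latent factor (pairwise correlation
    ``planted_rho``) so each also correlates marginally with y, as retained
    descriptors do in practice; remaining columns are independent noise.
    ``noise_sd`` defaults to 10% of the signal SD.  y is affinely placed at
    mean 0.5, SD 0.3 on the 10⁻⁴ mL/(mg·week) rate scale (the affine map
    preserves the planted linear law exactly).
    """
    if n_features < 3:
        raise ParameterError("need at least 3 features")
    if noise_sd is not None and noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    X = rng.standard_normal((n_molecules, n_features))
    planted_idx = np.sort(rng.choice(n_features, size=3, replace=False))
    latent = rng.standard_normal(n_molecules)
    for j in planted_idx:
        X[:, j] = np.sqrt(planted_rho) * latent + np.sqrt(1 - planted_rho) * (
            rng.standard_normal(n_molecules)
        )

    beta = np.asarray(coefficients, dtype=float)
    signal = X[:, planted_idx] @ beta
    sd_signal = signal.std()
    if noise_sd is None:
        noise_sd = 0.1 * sd_signal
    y_raw = signal + rng.normal(0.0, noise_sd, size=n_molecules)
    y = 0.5 + 0.3 * (y_raw - y_raw.mean()) / y_raw.std()

    grid = default_grid()
    name_idx = np.sort(rng.choice(len(grid), size=n_features, replace=False))
    columns = [grid[i].name for i in name_idx]
    mol_ids = [f"mAb{i + 1:02d}" for i in range(n_molecules)]
    Xdf = pd.DataFrame(X, index=mol_ids, columns=columns)
    planted_columns = tuple(columns[j] for j in planted_idx)
    return SyntheticStudy(
        X=Xdf,
        y=y,
        planted_columns=planted_columns,  # type: ignore[arg-type]
        coefficients=tuple(beta),  # type: ignore[arg-type]
        noise_sd=float(noise_sd),
        seed=seed,
    )
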