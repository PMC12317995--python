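"""Triangulated molecular surfaces and solvent-accessible surface area.

Two routes produce a :class:`SurfaceMesh`: importing MSMS ``.vert``/``.face``
output, or the native mesher, which triangulates the solvent-accessible
boundary (atom radii inflated by the probe) by marching cubes on a signed
distance grid.  SASA follows the Shrake–Rupley rolling-probe scheme with
test points from a Fibonacci sphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import MeshFormatError, ParameterError
from .structures import Structure

logger = logging.getLogger(__name__)


@dataclass
class SurfaceMesh:
    """Triangulated surface with per-point outward normals and area weights.

    ``area_weights`` allocate one third of each incident triangle's area to
    each of its vertices, so ``area_weights.sum()`` equals the total mesh
    area.  ``nearest_atom`` holds 0-based atom indices (-1 where unknown,
    e.g. analytic fixture meshes).
    """

    positions: np.ndarray  # (N, 3) Å
    normals: np.ndarray  # (N, 3) unit, outward
    triangles: np.ndarray  # (M, 3) int point indices
    nearest_atom: np.ndarray  # (N,) int
    area_weights: np.ndarray = field(default=None)  # (N,) Ų
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.nearest_atom = np.asarray(self.nearest_atom, dtype=int)
        n = len(self.positions)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise MeshFormatError("triangle indices out of range")
        norms = np.linalg.norm(self.normals, axis=1)
        bad = np.abs(norms - 1.0) > 1e-6
        if bad.any():
            logger.warning("renormalizing %d non-unit normals", int(bad.sum()))
            self.normals = self.normals / norms[:, None]
        if self.area_weights is None:
            self.area_weights = vertex_area_weights(self.positions, self.triangles)
        self._adjacency: list[np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def total_area(self) -> float:
        return float(self.area_weights.sum())

    @property
    def adjacency(self) -> list[np.ndarray]:
        """Symmetric vertex adjacency from triangle edges."""
        if self._adjacency is None:
            nbrs: list[set[int]] = [set() for _ in range(len(self))]
            for i, j, k in self.triangles:
                nbrs[i].update((j, k))
                nbrs[j].update((i, k))
                nbrs[k].update((i, j))
            self._adjacency = [np.fromiter(s, dtype=int) for s in nbrs]
        return self._adjacency


def vertex_area_weights(positions: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Barycentric third-of-triangle area allocation per vertex."""
    weights = np.zeros(len(positions))
    if len(triangles) == 0:
        return weights
    p = positions[triangles]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    for col in range(3):
        np.add.at(weights, triangles[:, col], areas / 3.0)
    return weights


# ---------------------------------------------------------------------------
# MSMS import
# ---------------------------------------------------------------------------


def _msms_data_lines(path: Path) -> tuple[int, list[list[str]]]:
    """Return the declared row count and data rows of an MSMS file.

    MSMS writes two '#' comment lines and a header line whose first integer
    is the row count; tolerate files without comments.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    lines = [ln for ln in lines if not ln.startswith("#")]
    if not lines:
        raise MeshFormatError(f"{path}: empty file")
    header = lines[0].split()
    try:
        count = int(header[0])
    except ValueError as exc:
        raise MeshFormatError(f"{path}: missing count header") from exc
    rows = [ln.split() for ln in lines[1:]]
    if len(rows) != count:
        raise MeshFormatError(
            f"{path}: header declares {count} rows, found {len(rows)}"
        )
    return count, rows


def import_msms(vert_path: str | Path, face_path: str | Path) -> SurfaceMesh:
    """Read an MSMS ``.vert``/``.face`` pair (1-based face indices).

    Vertex rows are ``x y z nx ny nz [flag sphere_index type]``; the sphere
    index (1-based nearest atom) is taken from column 8 when present.
    """
    n_verts, vrows = _msms_data_lines(Path(vert_path))
    n_faces, frows = _msms_data_lines(Path(face_path))

    positions = np.empty((n_verts, 3))
    normals = np.empty((n_verts, 3))
    nearest = np.full(n_verts, -1, dtype=int)
    for i, row in enumerate(vrows):
        if len(row) < 6:
            raise MeshFormatError(f"{vert_path}: vertex row {i} has <6 columns")
        positions[i] = [float(v) for v in row[:3]]
        normals[i] = [float(v) for v in row[3:6]]
        if len(row) >= 8:
            nearest[i] = int(row[7]) - 1

    triangles = np.empty((n_faces, 3), dtype=int)
    for i, row in enumerate(frows):
        if len(row) < 3:
            raise MeshFormatError(f"{face_path}: face row {i} has <3 columns")
        idx = [int(v) for v in row[:3]]
        if min(idx) < 1:
            raise MeshFormatError(
                f"{face_path}: face row {i} uses index {min(idx)} in a 1-based dialect"
            )
        if max(idx) > n_verts:
            raise MeshFormatError(f"{face_path}: face row {i} references vertex {max(idx)}")
        triangles[i] = [v - 1 for v in idx]

    return SurfaceMesh(
        positions=positions,
        normals=normals,
        triangles=triangles,
        nearest_atom=nearest,
        provenance={"source": "msms", "vert": str(vert_path), "face": str(face_path)},
    )


def export_off(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write the mesh as OFF for visual debugging."""
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(mesh)} {len(mesh.triangles)} 0\n")
        for p in mesh.positions:
            fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


# ---------------------------------------------------------------------------
# Native mesher (marching cubes on a signed-distance grid)
# ---------------------------------------------------------------------------


def build_surface(
    structure: Structure,
    probe_radius: float = 1.4,
    grid_spacing: float = 0.6,
) -> SurfaceMesh:
    """Triangulate the solvent-accessible boundary of a structure.

    The signed distance ``f(x) = min_i(|x - c_i| - (r_i + probe))`` is
    sampled on a regular grid and the zero level set extracted by marching
    cubes; normals come from the (outward-pointing) distance gradient.
    A single atom yields a sphere mesh; zero atoms is an error upstream.
    """
    if grid_spacing <= 0:
        raise ParameterError("grid_spacing must be positive")
    centers = structure.coords
    radii = structure.radii
    if not np.all(np.isfinite(radii)) or np.any(radii <= 0):
        raise ParameterError("all atoms need positive radii (run assign_parameters)")
    inflated = radii + probe_radius

    pad = inflated.max() + 3 * grid_spacing
    lo = centers.min(axis=0) - pad
    hi = centers.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / grid_spacing).astype(int) + 1, 2)
    axes = [lo[d] + grid_spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    dist = np.full(len(pts), np.inf)
    for c, ri in zip(centers, inflated):
        d = np.linalg.norm(pts - c, axis=1) - ri
        np.minimum(dist, d, out=dist)
    vol = dist.reshape(shape)

    from skimage.measure import marching_cubes

    verts, faces, grad_normals, _ = marching_cubes(
        vol, level=0.0, spacing=(grid_spacing,) * 3
    )
    verts = verts + lo

    tree = cKDTree(centers)
    # nearest atom by inflated-sphere distance: search a few candidates
    k = min(8, len(centers))
    d_cand, i_cand = tree.query(verts, k=k)
    d_cand = np.atleast_2d(d_cand.T).T
    i_cand = np.atleast_2d(i_cand.T).T
    eff = d_cand - inflated[i_cand]
    nearest = i_cand[np.arange(len(verts)), np.argmin(eff, axis=1)]

    # skimage normals follow the negative volume gradient; our signed distance
    # increases outward, so flip and renormalize
    normals = -grad_normals
    outward = np.einsum("ij,ij->i", normals, verts - centers[nearest])
    normals[outward < 0] *= -1
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    return SurfaceMesh(
        positions=verts,
        normals=normals,
        triangles=faces,
        nearest_atom=nearest,
        provenance={
            "source": "native-sas",
            "surface": "SAS",
            "probe_radius": probe_radius,
            "grid_spacing": grid_spacing,
        },
    )


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA
# ---------------------------------------------------------------------------


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors from the golden-angle spiral."""
    if n < 1:
        raise ParameterError("need at least one point")
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


@dataclass
class SasaResult:
    """Per-atom and total solvent-accessible surface area (Ų)."""

    per_atom: np.ndarray
    n_sphere_points: int
    probe_radius: float

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> SasaResult:
    """Shrake–Rupley SASA: per atom, the accessible fraction of Fibonacci
    test points on its probe-inflated sphere times ``4π(r_i + probe)²``."""
    if n_sphere_points < 16:
        raise ParameterError("n_sphere_points must be >= 16")
    centers = structure.coords
    radii = structure.radii
    if not np.all(np.isfinite(radii)) or np.any(radii <= 0):
        raise ParameterError("all atoms need positive radii (run assign_parameters)")
    inflated = radii + probe_radius
    dirs = fibonacci_sphere(n_sphere_points)
    tree = cKDTree(centers)
    per_atom = np.zeros(len(centers))
    max_reach = 2 * inflated.max()
    for i, (c, ri) in enumerate(zip(centers, inflated)):
        pts = c + ri * dirs
        neighbor_idx = [j for j in tree.query_ball_point(c, ri + max_reach) if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbor_idx:
            d = np.linalg.norm(pts - centers[j], axis=1)
            accessible &= d >= inflated[j]
            if not accessible.any():
                break
        per_atom[i] = accessible.mean() * 4.0 * np.pi * ri * ri
    return SasaResult(per_atom=per_atom, n_sphere_points=n_sphere_points, probe_radius=probe_radius)
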