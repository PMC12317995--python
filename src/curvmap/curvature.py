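"""Principal curvatures, shape index and curvedness on surface meshes.

At each mesh point the 1-ring neighborhood (extended to the 2-ring when
fewer than 5 neighbors are available) is projected into the tangent plane
and a quadric ``w = a u² + b u v + c v²`` fitted by least squares; the
principal curvatures are the (negated) eigenvalues of the second fundamental
form ``[[2a, b], [b, 2c]]``.  With outward normals this makes convex
protrusions positive.

Shape index s ∈ [-1, 1] and curvedness c ≥ 0 follow the Koenderink–van Doorn
parameterization:

    s = (2/π)·arctan((κ₁ + κ₂)/(κ₁ − κ₂)),   κ₁ ≥ κ₂
    c = sqrt((κ₁² + κ₂²)/2)

Orientation note: with κ₁ ≥ κ₂ the denominator κ₁ − κ₂ is non-negative, so
the sign of s equals the sign of the mean curvature — convex-outward regions
(protrusions) approach s = +1 and cavities s = -1.  The opposite printed
convention (denominator κ₂ − κ₁) exists in the literature; this package
commits to protrusion-positive throughout, which is the orientation the
penalty functions assume.  Umbilic points (κ₁ = κ₂ ≠ 0) take the continuous
limit s = ±1; flat points (κ₁ = κ₂ = 0) take s = 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParameterError
from .surfaces import SurfaceMesh

DEFAULT_CUTOFFS = (1.0, 5.0, 10.0)  # Å patch radii: ~atom, ~residue, ~residue+neighbors


@dataclass
class CurvatureField:
    """Per-point principal curvatures (κ₁ ≥ κ₂), shape index and curvedness.

    ``valid`` flags points with enough neighbors for the quadric fit;
    invalid points are excluded from patch averages and feature sums.
    """

    kappa1: np.ndarray
    kappa2: np.ndarray
    s: np.ndarray
    c: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.kappa1)


@dataclass
class PatchField:
    """Patch-averaged shape index / curvedness at one Euclidean cut-off."""

    cutoff: float
    s_bar: np.ndarray
    c_bar: np.ndarray
    valid: np.ndarray


def shape_index(kappa1, kappa2):
    """Shape index with κ₁ ≥ κ₂ (vectorized; see module docstring)."""
    k1 = np.asarray(kappa1, dtype=float)
    k2 = np.asarray(kappa2, dtype=float)
    num = k1 + k2
    den = k1 - k2
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (2.0 / np.pi) * np.arctan(num / den)
    s = np.where(den == 0.0, np.sign(num), s)
    return s if s.ndim else float(s)


def curvedness(kappa1, kappa2):
    """Root-mean-square curvature magnitude (1/Å)."""
    k1 = np.asarray(kappa1, dtype=float)
    k2 = np.asarray(kappa2, dtype=float)
    c = np.sqrt(0.5 * (k1 * k1 + k2 * k2))
    return c if c.ndim else float(c)


def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # any orthonormal tangent pair works: curvatures are frame-invariant
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def principal_curvatures(mesh: SurfaceMesh, min_neighbors: int = 5) -> CurvatureField:
    """Quadric-fit principal curvatures at every mesh point.

    Points whose (extended) neighborhood still has fewer than 3 neighbors are
    flagged invalid rather than raising, so a few degenerate vertices do not
    abort a whole-surface computation.
    """
    n = len(mesh)
    adjacency = mesh.adjacency
    positions = mesh.positions
    normals = mesh.normals
    kappa1 = np.zeros(n)
    kappa2 = np.zeros(n)
    valid = np.zeros(n, dtype=bool)

    for i in range(n):
        nbrs = adjacency[i]
        if len(nbrs) < min_neighbors:
            ring2: set[int] = set(nbrs)
            for j in nbrs:
                ring2.update(adjacency[j])
            ring2.discard(i)
            nbrs = np.fromiter(ring2, dtype=int)
        if len(nbrs) < 3:
            continue
        nrm = normals[i]
        e1, e2 = _tangent_frame(nrm)
        d = positions[nbrs] - positions[i]
        u = d @ e1
        v = d @ e2
        w = d @ nrm
        design = np.column_stack([u * u, u * v, v * v])
        try:
            coef, *_ = np.linalg.lstsq(design, w, rcond=None)
        except np.linalg.LinAlgError:
            continue
        a, b, c = coef
        # second fundamental form wrt the outward normal; negate so convex
        # (neighbors below the tangent plane) gives positive curvature
        mean = -(a + c)
        diff = np.sqrt((a - c) ** 2 + b * b)
        kappa1[i] = mean + diff
        kappa2[i] = mean - diff
        valid[i] = True

    s = shape_index(kappa1, kappa2)
    c = curvedness(kappa1, kappa2)
    s = np.where(valid, s, 0.0)
    c = np.where(valid, c, 0.0)
    return CurvatureField(kappa1=kappa1, kappa2=kappa2, s=s, c=c, valid=valid)


def patch_average(
    field: CurvatureField,
    mesh: SurfaceMesh,
    cutoff: float,
    area_weighted: bool = False,
) -> PatchField:
    """Mean s and c over the closed Euclidean ball of radius ``cutoff``.

    The point itself is always a member of its own patch, so the mean is
    defined everywhere; invalid points contribute to no patch.  The default
    is the unweighted mean over points; ``area_weighted=True`` weights each
    point by its area share.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    tree = cKDTree(mesh.positions)
    neighborhoods = tree.query_ball_point(mesh.positions, cutoff)
    n = len(mesh)
    s_bar = np.zeros(n)
    c_bar = np.zeros(n)
    weights = mesh.area_weights if area_weighted else np.ones(n)
    for i, nb in enumerate(neighborhoods):
        nb = np.asarray(nb, dtype=int)
        nb = nb[field.valid[nb]]
        if len(nb) == 0:
            continue
        w = weights[nb]
        wsum = w.sum()
        if wsum <= 0:
            nb_w = np.ones(len(nb)) / len(nb)
        else:
            nb_w = w / wsum
        s_bar[i] = float(nb_w @ field.s[nb])
        c_bar[i] = float(nb_w @ field.c[nb])
    return PatchField(cutoff=cutoff, s_bar=s_bar, c_bar=c_bar, valid=field.valid.copy())


def curvature_table(
    mesh: SurfaceMesh,
    field: CurvatureField,
    patches: dict[float, PatchField] | None = None,
) -> pd.DataFrame:
    """Tabulate per-point curvature values (CSV-ready export)."""
    data = {
        "point_id": np.arange(len(mesh)),
        "kappa1": field.kappa1,
        "kappa2": field.kappa2,
        "s": field.s,
        "c": field.c,
        "valid": field.valid,
    }
    if patches:
        for cutoff in sorted(patches):
            pf = patches[cutoff]
            data[f"s_bar@{cutoff:g}"] = pf.s_bar
            data[f"c_bar@{cutoff:g}"] = pf.c_bar
    return pd.DataFrame(data)
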