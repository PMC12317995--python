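"""Physico-chemical fields on surface points: hydrophobicity (MLP) and
electrostatic potential, each split into positive/negative channels.

The molecular lipophilicity potential at a surface point is the
Fermi-weighted convex combination of atomic hydrophobicities:

    MLP = Σᵢ pᵢ fᵢ,   pᵢ = g(dᵢ)/Σⱼ g(dⱼ),   g(d) = 1/(exp(1.5·(d − 4.0)) + 1)

with distances d in Å; the half-decay at 4 Å and the 1.5 Å⁻¹ steepness set
the range of the hydrophobic effect.

The electrostatic field has two modes.  ``screened_coulomb`` is an explicit
linearized Debye–Hückel sum over atomic point charges in a uniform solvent
dielectric — a stand-in that reduces to pure Coulomb at zero ionic strength
and is NOT a Poisson–Boltzmann solution (no low-dielectric protein cavity).
``grid_import`` interpolates an externally computed potential grid (OpenDX
dialect, as written by APBS/DelPhi) at the surface points; use it when a
real PB solution is required.  Potentials are reported in kT/e at the model
temperature either way, and the source is recorded in the property id's
provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import constants
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .errors import ConsistencyError, MeshFormatError, ParameterError
from .structures import Structure
from .surfaces import SurfaceMesh

logger = logging.getLogger(__name__)

MLP_STEEPNESS = 1.5  # 1/Å
MLP_MIDPOINT = 4.0  # Å
MLP_G_FLOOR = 1e-4  # atoms with g(d) below this are dropped from both sums


@dataclass
class SurfaceProperty:
    """A scalar field φ on mesh points plus its sign-split channels."""

    property_id: str  # "HCM (ww)" | "HCM (logP)" | "ECM"
    values: np.ndarray
    provenance: dict = field(default_factory=dict)
    phi_plus: np.ndarray | None = None
    phi_minus: np.ndarray | None = None

    def channel(self, signature: str) -> np.ndarray:
        """Return the '+' (φ⁺ = max(φ,0)) or '−' (φ⁻ = min(φ,0)) channel."""
        if self.phi_plus is None or self.phi_minus is None:
            sign_split(self)
        if signature == "+":
            return self.phi_plus
        if signature == "-":
            return self.phi_minus
        raise ParameterError(f"signature must be '+' or '-', got {signature!r}")


def sign_split(prop: SurfaceProperty) -> SurfaceProperty:
    """Populate φ⁺/φ⁻ channels in place (φ = φ⁺ + φ⁻ exactly)."""
    v = np.asarray(prop.values, dtype=float)
    prop.phi_plus = np.maximum(v, 0.0)
    prop.phi_minus = np.minimum(v, 0.0)
    return prop


def fermi_weight(d):
    """The MLP distance kernel g(d); g(4.0) = 1/2 exactly."""
    return 1.0 / (np.exp(MLP_STEEPNESS * (np.asarray(d, dtype=float) - MLP_MIDPOINT)) + 1.0)


def mlp_project(
    structure: Structure,
    mesh: SurfaceMesh,
    hydrophobicities: np.ndarray | None = None,
    property_id: str = "HCM (ww)",
    g_floor: float = MLP_G_FLOOR,
) -> SurfaceProperty:
    """Project atomic hydrophobicities onto the surface as MLP values.

    ``hydrophobicities`` overrides the per-atom values stored on the
    structure (used to evaluate several scales without re-assigning).  Atoms
    with kernel weight below ``g_floor`` are excluded from both numerator and
    denominator; the weights of the remainder are renormalized to sum to 1,
    so the projection stays a convex combination of the included fᵢ.
    """
    f = structure.hydrophobicities if hydrophobicities is None else np.asarray(
        hydrophobicities, dtype=float
    )
    if len(f) != len(structure):
        raise ConsistencyError("hydrophobicity vector length != atom count")
    if not np.all(np.isfinite(f)):
        raise ConsistencyError("hydrophobicities must be finite (assign_parameters)")
    centers = structure.coords
    # g(d) >= g_floor  <=>  d <= midpoint + ln(1/floor - 1)/steepness
    d_max = MLP_MIDPOINT + np.log(1.0 / g_floor - 1.0) / MLP_STEEPNESS
    tree = cKDTree(centers)
    neighborhoods = tree.query_ball_point(mesh.positions, d_max)
    values = np.empty(len(mesh))
    for i, nb in enumerate(neighborhoods):
        if not nb:  # far from every atom: fall back to the nearest one
            _, j = tree.query(mesh.positions[i])
            values[i] = f[j]
            continue
        nb = np.asarray(nb, dtype=int)
        d = np.linalg.norm(centers[nb] - mesh.positions[i], axis=1)
        g = fermi_weight(d)
        p = g / g.sum()
        values[i] = float(p @ f[nb])
    prop = SurfaceProperty(
        property_id=property_id,
        values=values,
        provenance={"kind": "mlp", "g_floor": g_floor},
    )
    return sign_split(prop)


# ---------------------------------------------------------------------------
# Electrostatics
# ---------------------------------------------------------------------------


@dataclass
class ElectrostaticModel:
    """Parameters of the surface-potential computation.

    ``eps_solvent``/``eps_protein`` are metadata describing the intended
    dielectric environment (the screened-Coulomb mode uses the solvent value
    only; a two-dielectric solution must come through ``grid_import``).
    """

    mode: str = "screened_coulomb"  # or "grid_import"
    ionic_strength: float = 0.15  # mol/L, 1:1 salt
    temperature: float = 298.0  # K
    eps_solvent: float = 80.0
    eps_protein: float = 4.0
    grid_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.ionic_strength < 0:
            raise ParameterError("ionic_strength must be >= 0")
        if self.temperature <= 0:
            raise ParameterError("temperature must be > 0")

    @property
    def bjerrum_length(self) -> float:
        """e²/(4π ε₀ ε_s k_B T) in Å (≈7.0 Å for water at 298 K)."""
        lb_m = constants.e**2 / (
            4.0
            * np.pi
            * constants.epsilon_0
            * self.eps_solvent
            * constants.k
            * self.temperature
        )
        return lb_m * 1e10

    @property
    def inverse_debye_length(self) -> float:
        """κ_D in 1/Å for a 1:1 electrolyte at the stored ionic strength."""
        # number density of charges (both ions), Å^-3
        n = 2.0 * self.ionic_strength * constants.N_A * 1e-27
        return float(np.sqrt(4.0 * np.pi * self.bjerrum_length * n))


MIN_CHARGE_DISTANCE = 0.1  # Å: clamp to avoid the point-charge singularity


def electrostatic_potential(
    structure: Structure,
    mesh: SurfaceMesh,
    model: ElectrostaticModel | None = None,
) -> SurfaceProperty:
    """Electrostatic potential at surface points, in kT/e.

    See the module docstring for the two modes and their fidelity.
    """
    model = ElectrostaticModel() if model is None else model
    if model.mode == "grid_import":
        if model.grid_path is None:
            raise ParameterError("grid_import mode requires grid_path")
        interp = _load_dx_interpolator(model.grid_path)
        values = interp(mesh.positions)
        provenance = {"kind": "potential", "source": str(model.grid_path)}
    elif model.mode == "screened_coulomb":
        q = structure.charges
        if not np.all(np.isfinite(q)):
            raise ConsistencyError("partial charges must be finite (assign_parameters)")
        lb = model.bjerrum_length
        kappa = model.inverse_debye_length
        centers = structure.coords
        values = np.zeros(len(mesh))
        # chunk over points to bound the distance-matrix memory
        chunk = max(1, 2_000_000 // max(len(centers), 1))
        for start in range(0, len(mesh), chunk):
            pts = mesh.positions[start : start + chunk]
            d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
            too_close = d < MIN_CHARGE_DISTANCE
            if too_close.any():
                logger.warning(
                    "%d point-charge distances < %.2f Å clamped",
                    int(too_close.sum()),
                    MIN_CHARGE_DISTANCE,
                )
                d = np.maximum(d, MIN_CHARGE_DISTANCE)
            values[start : start + chunk] = (np.exp(-kappa * d) / d) @ q * lb
        provenance = {
            "kind": "potential",
            "source": "screened_coulomb",
            "ionic_strength": model.ionic_strength,
            "temperature": model.temperature,
        }
    else:
        raise ParameterError(f"unknown electrostatic mode {model.mode!r}")
    prop = SurfaceProperty(property_id="ECM", values=np.asarray(values, dtype=float),
                           provenance=provenance)
    return sign_split(prop)


# ---------------------------------------------------------------------------
# OpenDX scalar grids
# ---------------------------------------------------------------------------


def read_opendx(path: str | Path):
    """Parse an OpenDX regular scalar grid (APBS/DelPhi-compatible dialect).

    Returns ``(origin, deltas, counts, data)`` with ``data`` shaped
    ``counts`` in x-fastest-last (C) order, as written by APBS.
    """
    counts = None
    origin = None
    deltas = []
    data: list[float] = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("object") and "gridpositions" in line:
                parts = line.split()
                counts = tuple(int(v) for v in parts[-3:])
            elif line.startswith("origin"):
                origin = np.array([float(v) for v in line.split()[1:4]])
            elif line.startswith("delta"):
                deltas.append([float(v) for v in line.split()[1:4]])
            elif line.startswith("object") and "class array" in line:
                in_data = True
            elif in_data:
                if line.startswith(("attribute", "component", "object")):
                    break
                data.extend(float(v) for v in line.split())
    if counts is None or origin is None or len(deltas) != 3:
        raise MeshFormatError(f"{path}: malformed OpenDX header")
    deltas = np.array(deltas)
    if not np.allclose(deltas, np.diag(np.diag(deltas))):
        raise MeshFormatError(f"{path}: only axis-aligned grids supported")
    n_expected = counts[0] * counts[1] * counts[2]
    if len(data) != n_expected:
        raise MeshFormatError(
            f"{path}: expected {n_expected} data values, found {len(data)}"
        )
    grid = np.asarray(data, dtype=float).reshape(counts)
    return origin, np.diag(deltas), np.array(counts), grid


def _load_dx_interpolator(path: str | Path) -> RegularGridInterpolator:
    origin, step, counts, grid = read_opendx(path)
    axes = [origin[d] + step[d] * np.arange(counts[d]) for d in range(3)]
    return RegularGridInterpolator(axes, grid, bounds_error=False, fill_value=0.0)
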