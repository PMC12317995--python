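"""Protein structures, trajectories, physico-chemical parameter assignment
and antibody region annotation.

Structures are read from PDB files (via biotite); every atom carries, after
:func:`assign_parameters`, a van-der-Waals radius, a partial charge ``Q_j``
(elementary charge units) and a normalized hydrophobicity ``f_i`` in
``[-1, 1]``.  Antibody regions (Fv, CDR, CDRH1-3, CDRL1-3) are annotated from
user-supplied residue-range files; the label closure CDRxN ⊂ CDR ⊂ Fv is
enforced.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    AnnotationError,
    AtomTypingError,
    EmptyStructureError,
    StructureFormatError,
    TrajectoryConsistencyError,
)

logger = logging.getLogger(__name__)

#: residue_id = (chain, residue number, insertion code)
ResidueId = tuple[str, int, str]

REGION_LABELS = (
    "Fv",
    "CDR",
    "CDRH1",
    "CDRH2",
    "CDRH3",
    "CDRL1",
    "CDRL2",
    "CDRL3",
)

AROMATIC_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}

_POLAR_H_PARTNERS = ("N", "O", "S")


@dataclass
class AtomRecord:
    """One atom with coordinates and assigned physico-chemical parameters."""

    atom_id: int
    element: str
    name: str
    coords: np.ndarray
    residue_id: ResidueId
    residue_name: str
    radius: float = np.nan
    partial_charge: float = np.nan
    hydrophobicity: float = np.nan

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureFormatError(
                f"atom {self.atom_id}: coordinates must be a finite 3-vector"
            )


@dataclass
class Structure:
    """An ordered collection of atoms (one frame)."""

    atoms: list[AtomRecord]
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError("structure contains no atoms")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise StructureFormatError("duplicate atom_ids in structure")

    def __len__(self) -> int:
        return len(self.atoms)

    # -- cached array views -------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def hydrophobicities(self) -> np.ndarray:
        return np.array([a.hydrophobicity for a in self.atoms], dtype=float)

    @property
    def residue_ids(self) -> list[ResidueId]:
        return [a.residue_id for a in self.atoms]

    def chains(self) -> set[str]:
        return {a.residue_id[0] for a in self.atoms}


@dataclass
class Trajectory:
    """Ordered frames sharing atom identity (e.g. MD snapshots)."""

    frames: list[Structure]
    time_step_label: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryConsistencyError("trajectory has no frames")
        ref = [(a.name, a.residue_id) for a in self.frames[0].atoms]
        for k, fr in enumerate(self.frames[1:], start=1):
            ident = [(a.name, a.residue_id) for a in fr.atoms]
            if ident != ref:
                raise TrajectoryConsistencyError(
                    f"frame {k} atom identity differs from frame 0"
                )

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _atom_array_to_structure(arr, frame_index: int = 0) -> Structure:
    atoms = []
    ins = (
        arr.ins_code
        if "ins_code" in arr.get_annotation_categories()
        else [""] * arr.array_length()
    )
    for i in range(arr.array_length()):
        atoms.append(
            AtomRecord(
                atom_id=i + 1,
                element=str(arr.element[i]).upper(),
                name=str(arr.atom_name[i]),
                coords=np.asarray(arr.coord[i], dtype=float),
                residue_id=(str(arr.chain_id[i]), int(arr.res_id[i]), str(ins[i]).strip()),
                residue_name=str(arr.res_name[i]),
            )
        )
    return Structure(atoms=atoms, frame_index=frame_index)


def read_structure(path: str | Path) -> Structure:
    """Read the first model of a PDB file into a :class:`Structure`."""
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except EmptyStructureError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        if _pdb_has_no_atoms(path):
            raise EmptyStructureError(f"{path} contains no ATOM/HETATM records")
        raise StructureFormatError(f"cannot parse PDB {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise EmptyStructureError(f"{path} contains no ATOM/HETATM records")
    return _atom_array_to_structure(arr)


def _pdb_has_no_atoms(path: Path) -> bool:
    try:
        with open(path) as fh:
            return not any(
                line.startswith(("ATOM", "HETATM")) for line in fh
            )
    except OSError:
        return False


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one frame per MODEL)."""
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        frames = []
        for m in range(1, n_models + 1):
            arr = pdb.get_structure(model=m)
            if arr.array_length() == 0:
                raise EmptyStructureError(f"model {m} of {path} is empty")
            frames.append(_atom_array_to_structure(arr, frame_index=m - 1))
    except (EmptyStructureError, TrajectoryConsistencyError):
        raise
    except Exception as exc:  # noqa: BLE001
        raise StructureFormatError(f"cannot parse PDB {path}: {exc}") from exc
    counts = {len(fr) for fr in frames}
    if len(counts) > 1:
        raise TrajectoryConsistencyError(
            f"models of {path} have differing atom counts: {sorted(counts)}"
        )
    return Trajectory(frames=frames, time_step_label=str(path.name))


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure back to PDB (coordinates at standard 3-decimal precision)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arr = struc.AtomArray(len(structure))
    for i, a in enumerate(structure.atoms):
        arr.coord[i] = a.coords
        arr.chain_id[i] = a.residue_id[0]
        arr.res_id[i] = a.residue_id[1]
        arr.ins_code[i] = a.residue_id[2]
        arr.res_name[i] = a.residue_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_pqr(path: str | Path) -> Structure:
    """Read a whitespace-separated PQR file (charges + radii included)."""
    atoms = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            parts = line.split()
            if len(parts) < 10:
                raise StructureFormatError(f"short PQR record: {line.rstrip()}")
            # name, resname, chain, resnum may lack chain column; handle both
            try:
                if parts[4].isalpha() and len(parts[4]) == 1:
                    chain, resnum, rest = parts[4], int(parts[5]), parts[6:]
                else:
                    chain, resnum, rest = "", int(parts[4]), parts[5:]
                x, y, z, q, r = (float(v) for v in rest[:5])
            except (ValueError, IndexError) as exc:
                raise StructureFormatError(
                    f"bad PQR record: {line.rstrip()}"
                ) from exc
            atoms.append(
                AtomRecord(
                    atom_id=int(parts[1]),
                    element=parts[2][0],
                    name=parts[2],
                    coords=np.array([x, y, z]),
                    residue_id=(chain, resnum, ""),
                    residue_name=parts[3],
                    radius=r,
                    partial_charge=q,
                )
            )
    if not atoms:
        raise EmptyStructureError(f"{path} contains no ATOM/HETATM records")
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# Hydrophobicity scales
# ---------------------------------------------------------------------------


def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    with resources.files("curvmap.data").joinpath(name).open() as fh:
        rows = [r for r in csv.DictReader(
            line for line in fh if not line.startswith("#")
        )]
    return rows


@dataclass
class HydrophobicityScale:
    """A residue- or atom-class-level hydrophobicity lookup.

    ``normalized(key)`` applies the stored affine map sending the raw
    min/max over the lookup domain to [-1, +1]; the parameters are kept so a
    given table always normalizes identically.
    """

    scale_id: str  # "ww" | "logP"
    granularity: str  # "per-residue" | "per-atom"
    values: dict[str, float]
    norm_offset: float = field(init=False)
    norm_scale: float = field(init=False)

    def __post_init__(self) -> None:
        vmin = min(self.values.values())
        vmax = max(self.values.values())
        if vmax == vmin:
            raise ValueError("degenerate scale: all values equal")
        # affine map: f = (v - offset) * scale  with f(vmin) = -1, f(vmax) = +1
        self.norm_offset = 0.5 * (vmin + vmax)
        self.norm_scale = 2.0 / (vmax - vmin)

    def normalized(self, key: str) -> float:
        return (self.values[key] - self.norm_offset) * self.norm_scale

    def __contains__(self, key: str) -> bool:
        return key in self.values


def load_scale(scale_id: str) -> HydrophobicityScale:
    """Load a packaged hydrophobicity scale: ``"ww"`` (residue-level
    interfacial scale) or ``"logP"`` (atomic logP-contribution classes)."""
    if scale_id == "ww":
        rows = _read_packaged_csv("wimley_white.csv")
        values = {r["residue"]: float(r["value"]) for r in rows}
        return HydrophobicityScale("ww", "per-residue", values)
    if scale_id == "logP":
        rows = _read_packaged_csv("wildman_crippen_classes.csv")
        values = {r["atom_class"]: float(r["value"]) for r in rows}
        return HydrophobicityScale("logP", "per-atom", values)
    raise ValueError(f"unknown scale_id {scale_id!r} (expected 'ww' or 'logP')")


def atom_class(residue_name: str, atom_name: str, element: str) -> str:
    """Heuristic atom-class typer for the atomic logP scale.

    Classifies carbons as aromatic (ring atoms of PHE/TYR/TRP/HIS), backbone
    carbonyl (name ``C``) or aliphatic; N/O/S/P/H by element with hydroxyl vs
    carbonyl oxygens split on atom name.
    """
    element = element.upper()
    ring = AROMATIC_RING_ATOMS.get(residue_name, set())
    if element == "C":
        if atom_name in ring:
            return "C_AROMATIC"
        if atom_name == "C":
            return "C_CARBONYL"
        return "C_ALIPHATIC"
    if element == "N":
        return "N_POLAR"
    if element == "O":
        return "O_CARBONYL" if atom_name in ("O", "OXT") else "O_HYDROXYL"
    if element == "S":
        return "S_ANY"
    if element == "P":
        return "P_ANY"
    if element == "H":
        # crude: hydrogens named after a polar partner (e.g. HG1 on SER OG)
        stripped = atom_name.lstrip("0123456789H")
        if stripped[:1] in _POLAR_H_PARTNERS:
            return "H_POLAR"
        return "H_ON_C"
    return ""


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------


def load_charge_table() -> dict[tuple[str, str], float]:
    rows = _read_packaged_csv("partial_charges.csv")
    return {(r["residue"], r["atom_name"]): float(r["charge"]) for r in rows}


def load_radius_table() -> dict[str, float]:
    rows = _read_packaged_csv("vdw_radii.csv")
    return {r["element"]: float(r["radius"]) for r in rows}


DEFAULT_RADIUS = 1.7  # fallback for unknown elements (non-strict mode), Å


def assign_parameters(
    structure: Structure,
    charges: Mapping[tuple[str, str], float] | None = None,
    scale: HydrophobicityScale | None = None,
    radii: Mapping[str, float] | None = None,
    strict: bool = False,
) -> Structure:
    """Populate radius, partial charge and normalized hydrophobicity.

    Idempotent: re-running with the same tables reproduces the same values.
    In strict mode an unresolvable atom raises :class:`AtomTypingError`;
    otherwise a fallback radius / zero charge / element-level hydrophobicity
    is used with a logged warning.
    """
    charges = load_charge_table() if charges is None else charges
    radii = load_radius_table() if radii is None else radii
    scale = load_scale("ww") if scale is None else scale

    new_atoms = []
    for a in structure.atoms:
        elem = a.element.upper()
        if elem in radii:
            radius = radii[elem]
        elif strict:
            raise AtomTypingError(f"no radius for element {elem!r} (atom {a.name})")
        else:
            logger.warning("no radius for element %r; using %.2f Å", elem, DEFAULT_RADIUS)
            radius = DEFAULT_RADIUS
        q = charges.get((a.residue_name, a.name), charges.get(("ANY", a.name), 0.0))
        if scale.granularity == "per-residue":
            if a.residue_name in scale:
                f = scale.normalized(a.residue_name)
            elif strict:
                raise AtomTypingError(
                    f"residue {a.residue_name!r} missing from scale {scale.scale_id}"
                )
            else:
                logger.warning(
                    "residue %r not in scale %s; hydrophobicity set to 0",
                    a.residue_name,
                    scale.scale_id,
                )
                f = 0.0
        else:
            cls = atom_class(a.residue_name, a.name, a.element)
            if cls in scale:
                f = scale.normalized(cls)
            elif strict:
                raise AtomTypingError(
                    f"atom {a.residue_name}/{a.name} untypeable for scale "
                    f"{scale.scale_id}"
                )
            else:
                logger.warning(
                    "atom %s/%s untypeable; hydrophobicity set to 0",
                    a.residue_name,
                    a.name,
                )
                f = 0.0
        new_atoms.append(replace(a, radius=radius, partial_charge=q, hydrophobicity=f))
    return Structure(atoms=new_atoms, frame_index=structure.frame_index)


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------


@dataclass
class RegionAnnotation:
    """residue_id → set of region labels, with CDRxN ⊂ CDR ⊂ Fv closure."""

    labels: dict[ResidueId, frozenset[str]]

    def labels_for(self, residue_id: ResidueId) -> frozenset[str]:
        return self.labels.get(residue_id, frozenset())

    def residues_with(self, label: str) -> set[ResidueId]:
        return {rid for rid, labs in self.labels.items() if label in labs}


def _close_labels(labels: set[str]) -> frozenset[str]:
    out = set(labels)
    if any(lab.startswith("CDR") and lab != "CDR" for lab in out):
        out.add("CDR")
    if "CDR" in out:
        out.add("Fv")
    return frozenset(out)


def read_region_definitions(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Read a region CSV (columns label,chain,start,end; '#' comments)."""
    defs = []
    with open(path) as fh:
        reader = csv.DictReader(line for line in fh if not line.startswith("#"))
        for row in reader:
            label = row["label"].strip()
            if label not in REGION_LABELS:
                raise AnnotationError(f"unknown region label {label!r}")
            defs.append(
                (label, row["chain"].strip(), int(row["start"]), int(row["end"]))
            )
    return defs


def annotate_regions(
    structure: Structure,
    region_defs: str | Path | Sequence[tuple[str, str, int, int]],
) -> RegionAnnotation:
    """Label residues inside each declared (chain, start-end) range.

    Accepts a CSV path or an in-memory list of ``(label, chain, start, end)``.
    A range naming a chain absent from the structure raises
    :class:`AnnotationError`.
    """
    if isinstance(region_defs, (str, Path)):
        region_defs = read_region_definitions(region_defs)
    chains = structure.chains()
    raw: dict[ResidueId, set[str]] = {rid: set() for rid in set(structure.residue_ids)}
    for label, chain, start, end in region_defs:
        if chain not in chains:
            raise AnnotationError(
                f"region {label} references chain {chain!r} absent from structure"
            )
        for rid in raw:
            if rid[0] == chain and start <= rid[1] <= end:
                raw[rid].add(label)
    return RegionAnnotation(labels={rid: _close_labels(labs) for rid, labs in raw.items()})
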