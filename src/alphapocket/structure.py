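"""Weighted atomic structures, trajectories, and binding-site selection.

Atoms carry a van der Waals radius and an alpha-shape weight
``w = (r + probe)**2`` (squared solvent-expanded radius, Å²), the standard
weighting for molecular alpha shapes.  Structures are read from PDB files
(single- or multi-model); a multi-model PDB is interpreted as a trajectory,
one frame per MODEL block.

The binding site is a fixed set of residues, chosen once on a reference
structure (either an explicit residue list or every residue with a heavy atom
within a cutoff of the ligand) and then reused, by residue key, for every
frame and every variant of the structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: Bondi van der Waals radii, Å.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "HE": 1.40,
    "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "NE": 1.54, "SI": 2.10, "P": 1.80, "S": 1.80, "CL": 1.75, "AR": 1.88,
    "K": 2.75, "BR": 1.85, "SE": 1.90, "I": 1.98, "XE": 2.16,
    "ZN": 1.39, "CU": 1.40, "NI": 1.63, "MG": 1.73, "NA": 2.27, "LI": 1.82,
}

DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_FALLBACK_RADIUS = 1.7  # Å, for elements missing from the table
WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP3"})


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be parsed."""


def vdw_radius(element: str, fallback: float | None = DEFAULT_FALLBACK_RADIUS) -> float:
    """Bondi radius for *element*; *fallback* if unknown (``None`` → error)."""
    r = BONDI_RADII.get(element.strip().upper())
    if r is None:
        if fallback is None:
            raise KeyError(f"no van der Waals radius for element {element!r} "
                           "and no fallback configured")
        return fallback
    return r


@dataclass(frozen=True)
class WeightedAtom:
    """A single atom with position, vdW radius, and alpha-shape weight.

    ``weight = (radius + probe_radius)**2`` in Å²; the squared radius of the
    solvent-expanded sphere the weighted alpha shape is built from.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray
    radius: float
    weight: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"atom {self.serial}: radius must be positive")
        if self.weight < self.radius ** 2 - 1e-12:
            raise ValueError(f"atom {self.serial}: weight {self.weight} < radius²")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position")


@dataclass
class Structure:
    """An ordered collection of weighted atoms, optionally with a bound ligand."""

    atoms: list[WeightedAtom]
    ligand_atoms: list[WeightedAtom] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials are not unique")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinates, Å."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        """(N,) alpha-shape weights, Å²."""
        return np.array([a.weight for a in self.atoms], dtype=float)

    @property
    def ligand_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.ligand_atoms], dtype=float).reshape(-1, 3)

    def residue_key(self, i: int) -> tuple[str, int]:
        a = self.atoms[i]
        return (a.chain, a.residue_id)

    def to_dataframe(self, site: "BindingSite | None" = None) -> pd.DataFrame:
        """Per-atom summary table; flags site membership if *site* given."""
        in_site = set(site.atom_indices.tolist()) if site is not None else set()
        rows = [
            {
                "serial": a.serial, "name": a.name, "element": a.element,
                "residue_name": a.residue_name, "residue_id": a.residue_id,
                "chain": a.chain, "x": a.position[0], "y": a.position[1],
                "z": a.position[2], "radius": a.radius, "weight": a.weight,
                "in_site": i in in_site,
            }
            for i, a in enumerate(self.atoms)
        ]
        return pd.DataFrame(rows)


@dataclass
class Trajectory:
    """A topology plus F coordinate frames.

    ``frames[f]`` is an (N, 3) array aligned with ``topology.atoms``;
    ``frame_spacing`` is the sampling interval in picoseconds.
    """

    topology: Structure
    frames: np.ndarray  # (F, N, 3)
    frame_spacing: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Span covered by the sampled frames, ps (n_frames × spacing)."""
        return self.n_frames * self.frame_spacing


@dataclass
class BindingSite:
    """A fixed residue-level site with its atom indices on one structure."""

    residue_keys: list[tuple[str, int]]
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        if self.atom_indices.size == 0:
            raise ValueError("binding site has no atoms")
        if len(set(self.atom_indices.tolist())) != self.atom_indices.size:
            raise ValueError("binding site atom indices are not unique")

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    @property
    def n_atoms(self) -> int:
        return int(self.atom_indices.size)

    def resolve(self, structure: Structure) -> "BindingSite":
        """Map this site, by residue key, onto another structure.

        The same residues are looked up in *structure*; their heavy atoms (in
        file order) become the new ``atom_indices``.  Residues absent from
        *structure* are an error.
        """
        keys = set(self.residue_keys)
        idx = [i for i in range(structure.n_atoms) if structure.residue_key(i) in keys]
        found = {structure.residue_key(i) for i in idx}
        missing = keys - found
        if missing:
            raise ValueError(f"residues missing from structure: {sorted(missing)}")
        return BindingSite(residue_keys=list(self.residue_keys),
                           atom_indices=np.array(idx, dtype=int))


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _locate_bad_coordinate_line(path: Path) -> int | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        return lineno
    return None


def _atoms_from_array(arr: bst.AtomArray, serials: np.ndarray,
                      probe_radius: float, fallback_radius: float | None) -> list[WeightedAtom]:
    out = []
    for i in range(arr.array_length()):
        r = vdw_radius(arr.element[i], fallback_radius)
        out.append(WeightedAtom(
            serial=int(serials[i]), name=str(arr.atom_name[i]),
            element=str(arr.element[i]).upper(),
            residue_name=str(arr.res_name[i]), residue_id=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]) or "A",
            position=arr.coord[i].astype(float).copy(),
            radius=r, weight=(r + probe_radius) ** 2,
        ))
    return out


def _load_pdb(path: str | Path) -> PDBFile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite reads lazily
        raise PDBFormatError(f"{path}: cannot read PDB file: {exc}") from exc


def _split_masks(arr: bst.AtomArray, ligand_resname: str | None,
                 drop_hydrogens: bool) -> tuple[np.ndarray, np.ndarray]:
    """(protein_mask, ligand_mask) after water/hydrogen filtering."""
    keep = ~np.isin(arr.res_name, list(WATER_RESNAMES))
    if drop_hydrogens:
        keep &= ~np.isin(np.char.upper(arr.element.astype(str)), ["H", "D"])
    lig = np.zeros(arr.array_length(), dtype=bool)
    if ligand_resname is not None:
        lig = keep & (arr.res_name == ligand_resname) & arr.hetero
    return keep & ~lig, lig


def read_pdb(path: str | Path, model: int | None = None, *,
             probe_radius: float = DEFAULT_PROBE_RADIUS,
             ligand_resname: str | None = None,
             drop_hydrogens: bool = True,
             fallback_radius: float | None = DEFAULT_FALLBACK_RADIUS) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Parameters
    ----------
    model
        1-based model number; ``None`` reads the first model.
    ligand_resname
        HETATM residue name routed to ``Structure.ligand_atoms``
        (e.g. gefitinib's chemical id in EGFR kinase-domain entries).
    drop_hydrogens
        Keep heavy atoms only (the geometric convention for molecular
        alpha shapes).  Waters are always dropped.
    """
    path = Path(path)
    pdb = _load_pdb(path)
    try:
        arr = pdb.get_structure(model=model if model is not None else 1)
    except Exception as exc:
        lineno = _locate_bad_coordinate_line(path)
        if lineno is not None:
            raise PDBFormatError(
                f"{path}: unparseable coordinate field at line {lineno}") from exc
        raise PDBFormatError(f"{path}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records")
    serials = np.arange(1, arr.array_length() + 1)
    prot_mask, lig_mask = _split_masks(arr, ligand_resname, drop_hydrogens)
    atoms = _atoms_from_array(arr[prot_mask], serials[prot_mask],
                              probe_radius, fallback_radius)
    ligand = _atoms_from_array(arr[lig_mask], serials[lig_mask],
                               probe_radius, fallback_radius)
    return Structure(atoms=atoms, ligand_atoms=ligand, label=path.stem)


def _model_atom_counts(path: Path) -> list[int]:
    counts, current, in_model, saw_model = [], 0, False, False
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                saw_model, in_model, current = True, True, 0
            elif line.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif line.startswith(("ATOM  ", "HETATM")):
                current += 1
                if not saw_model:
                    in_model = True
    if saw_model and in_model:  # unterminated final MODEL
        counts.append(current)
    if not saw_model:
        counts = [current] if current else []
    return counts


def read_trajectory(path: str | Path, frame_spacing: float = 10.0, *,
                    probe_radius: float = DEFAULT_PROBE_RADIUS,
                    ligand_resname: str | None = None,
                    drop_hydrogens: bool = True,
                    fallback_radius: float | None = DEFAULT_FALLBACK_RADIUS) -> Trajectory:
    """Read a multi-model PDB as a trajectory, one frame per MODEL block.

    The topology (atom identities, radii, weights) comes from the first
    model; every model must contain the same number of atoms.
    """
    path = Path(path)
    pdb = _load_pdb(path)
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        counts = _model_atom_counts(path)
        if len(set(counts)) > 1:
            bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
            raise PDBFormatError(
                f"{path}: model {bad} has {counts[bad - 1]} atoms, expected "
                f"{counts[0]}") from exc
        lineno = _locate_bad_coordinate_line(path)
        if lineno is not None:
            raise PDBFormatError(
                f"{path}: unparseable coordinate field at line {lineno}") from exc
        raise PDBFormatError(f"{path}: {exc}") from exc
    if isinstance(stack, bst.AtomArray):  # single model, no MODEL records
        stack = bst.stack([stack])
    first = stack[0]
    serials = np.arange(1, first.array_length() + 1)
    prot_mask, lig_mask = _split_masks(first, ligand_resname, drop_hydrogens)
    topology = Structure(
        atoms=_atoms_from_array(first[prot_mask], serials[prot_mask],
                                probe_radius, fallback_radius),
        ligand_atoms=_atoms_from_array(first[lig_mask], serials[lig_mask],
                                       probe_radius, fallback_radius),
        label=path.stem)
    frames = stack.coord[:, prot_mask, :].astype(float)
    return Trajectory(topology=topology, frames=frames, frame_spacing=frame_spacing)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _to_atom_array(structure: Structure, coords: np.ndarray | None = None) -> bst.AtomArray:
    atoms = structure.atoms + structure.ligand_atoms
    n = len(atoms)
    arr = bst.AtomArray(n)
    if coords is None:
        coords = np.array([a.position for a in atoms], dtype=float)
    arr.coord = np.asarray(coords, dtype=np.float32).reshape(n, 3)
    arr.chain_id = np.array([a.chain for a in atoms])
    arr.res_id = np.array([a.residue_id for a in atoms])
    arr.res_name = np.array([a.residue_name for a in atoms])
    arr.atom_name = np.array([a.name for a in atoms])
    arr.element = np.array([a.element for a in atoms])
    arr.hetero = np.array([False] * len(structure.atoms)
                          + [True] * len(structure.ligand_atoms))
    return arr


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure (protein atoms then ligand atoms) as a PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL block per frame)."""
    top = traj.topology
    n_lig = len(top.ligand_atoms)
    lig = np.array([a.position for a in top.ligand_atoms], dtype=float).reshape(n_lig, 3)
    coords = np.concatenate(
        [traj.frames, np.broadcast_to(lig, (traj.n_frames, n_lig, 3))], axis=1)
    template = _to_atom_array(top)
    stack = bst.AtomArrayStack(traj.n_frames, template.array_length())
    stack.coord = coords.astype(np.float32)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Binding-site selection
# ---------------------------------------------------------------------------

def select_binding_site(reference: Structure,
                        mode: Literal["residue-list", "ligand-cutoff"] = "ligand-cutoff",
                        residues: Sequence[tuple[str, int]] | None = None,
                        cutoff: float = 5.0) -> BindingSite:
    """Define the binding site on a reference structure.

    ``ligand-cutoff`` selects every residue with at least one heavy atom
    within *cutoff* Å of any ligand heavy atom, then includes ALL heavy atoms
    of those residues.  ``residue-list`` takes the ``(chain, residue_id)``
    keys verbatim.  The returned site is meant to be fixed once on the
    reference and re-applied (via :meth:`BindingSite.resolve`) to every other
    structure and frame.
    """
    if mode == "residue-list":
        if not residues:
            raise ValueError("residue-list mode requires a residue list")
        keys = [(str(c), int(r)) for c, r in residues]
        site = BindingSite(residue_keys=keys, atom_indices=np.array([0]))
        return site.resolve(reference)
    if mode != "ligand-cutoff":
        raise ValueError(f"unknown site mode {mode!r}")
    if not reference.ligand_atoms:
        raise ValueError("ligand-cutoff mode requires ligand atoms")
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    dmin = cdist(reference.positions, reference.ligand_positions).min(axis=1)
    hit_keys: list[tuple[str, int]] = []
    seen = set()
    for i in np.nonzero(dmin <= cutoff)[0]:
        key = reference.residue_key(int(i))
        if key not in seen:
            seen.add(key)
            hit_keys.append(key)
    if not hit_keys:
        raise ValueError(
            f"no residue within {cutoff} Å of the ligand; enlarge the cutoff "
            "or give an explicit residue list")
    idx = [i for i in range(reference.n_atoms) if reference.residue_key(i) in seen]
    return BindingSite(residue_keys=hit_keys, atom_indices=np.array(idx, dtype=int))
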