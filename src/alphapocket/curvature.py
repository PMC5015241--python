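"""Per-atom solid-angle curvature on the alpha-shape surface.

Each surface atom gets a dimensionless curvature score SA ∈ [−1, 1]:

    SA = 1 − Ω_int / (2π)

where Ω_int is the solid angle (steradians) that the molecule's body — the
member tetrahedra of the alpha complex — subtends at the atom's center.  An
isolated bump sees no interior (Ω_int = 0, SA = +1); a locally flat surface
sees a half-space (Ω_int = 2π, SA = 0); an atom at the bottom of a cavity
sees more than a half-space (SA < 0); a fully enclosed atom sees everything
(Ω_int = 4π, SA = −1).  SA ∈ (0, 1] is convex, SA ∈ [−1, 0) concave.  Atoms
not on the surface (buried, or hidden weighted points) are assigned SA = 0
with ``surface_flag = False``.

For a trajectory, the weighted alpha complex of ALL protein heavy atoms is
rebuilt at every frame and the binding-site atoms are scored, giving an
F × A matrix of SA values (F frames, A site atoms) — the per-frame curvature
profile that the knob-level statistics summarize.  The bound drug is not
part of the shape: pocket curvature is a property of the protein alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphashape import AlphaComplex, build_alpha_complex, surface_atoms
from .structure import BindingSite, Structure, Trajectory

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi
#: Tolerated floating-point excursion of |SA| beyond 1 before clamping fails.
SA_CONSISTENCY_TOL = 1e-6


@dataclass(frozen=True)
class SolidAngleValue:
    """Curvature of one binding-site atom in one frame."""

    atom_index: int
    frame_index: int
    sa: float
    surface_flag: bool


@dataclass
class CurvatureProfile:
    """SA[f, a] for F frames × A binding-site atoms (column order = site order)."""

    sa_matrix: np.ndarray          # (F, A)
    surface_flags: np.ndarray      # (F, A) bool
    site: BindingSite
    frame_spacing: float = 10.0

    def __post_init__(self) -> None:
        self.sa_matrix = np.asarray(self.sa_matrix, dtype=float)
        self.surface_flags = np.asarray(self.surface_flags, dtype=bool)
        if self.sa_matrix.shape != self.surface_flags.shape:
            raise ValueError("sa_matrix and surface_flags shapes differ")
        if self.sa_matrix.ndim != 2:
            raise ValueError("sa_matrix must be 2-D (frames × atoms)")
        if self.sa_matrix.shape[1] != self.site.n_atoms:
            raise ValueError("column count must match the binding site")
        if np.any(np.abs(self.sa_matrix) > 1.0 + SA_CONSISTENCY_TOL):
            raise ValueError("SA values outside [-1, 1]")

    @property
    def n_frames(self) -> int:
        return self.sa_matrix.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.sa_matrix.shape[1]

    def to_dataframe(self, structure: Structure | None = None) -> pd.DataFrame:
        """Long-format table: frame, site atom, SA, surface flag."""
        f_idx, a_idx = np.meshgrid(np.arange(self.n_frames),
                                   np.arange(self.n_atoms), indexing="ij")
        df = pd.DataFrame({
            "frame": f_idx.ravel(),
            "site_atom": a_idx.ravel(),
            "atom_index": self.site.atom_indices[a_idx.ravel()],
            "sa": self.sa_matrix.ravel(),
            "surface": self.surface_flags.ravel(),
        })
        if structure is not None:
            atoms = [structure.atoms[i] for i in df["atom_index"]]
            df["serial"] = [a.serial for a in atoms]
            df["residue"] = [f"{a.residue_name}{a.residue_id}" for a in atoms]
        return df


def profile_from_csv(path) -> CurvatureProfile:
    """Rebuild a :class:`CurvatureProfile` from its long-format CSV export."""
    df = pd.read_csv(path)
    frames = np.sort(df["frame"].unique())
    atoms = np.sort(df["site_atom"].unique())
    piv = df.pivot(index="frame", columns="site_atom", values="sa").loc[frames, atoms]
    flg = df.pivot(index="frame", columns="site_atom", values="surface").loc[frames, atoms]
    atom_idx = (df.drop_duplicates("site_atom").sort_values("site_atom")
                ["atom_index"].to_numpy(dtype=int))
    site = BindingSite(residue_keys=[("A", int(i)) for i in atom_idx],
                       atom_indices=atom_idx)
    return CurvatureProfile(sa_matrix=piv.to_numpy(dtype=float),
                            surface_flags=flg.to_numpy(dtype=bool), site=site)


def solid_angle_batch(apex: np.ndarray, a: np.ndarray, b: np.ndarray,
                      c: np.ndarray) -> np.ndarray:
    """Solid angles subtended at ``apex[i]`` by triangles ``(a[i], b[i], c[i])``.

    Van Oosterom–Strackee atan2 formula; results in [0, 2π).  Triangles
    coplanar with their apex contribute 0.
    """
    va, vb, vc = a - apex, b - apex, c - apex
    la = np.linalg.norm(va, axis=-1)
    lb = np.linalg.norm(vb, axis=-1)
    lc = np.linalg.norm(vc, axis=-1)
    triple = np.einsum("...i,...i->...", va, np.cross(vb, vc))
    denom = (la * lb * lc + np.einsum("...i,...i->...", va, vb) * lc
             + np.einsum("...i,...i->...", va, vc) * lb
             + np.einsum("...i,...i->...", vb, vc) * la)
    omega = 2.0 * np.arctan2(np.abs(triple), denom)
    omega = np.where(omega < 0, omega + 2.0 * TWO_PI, omega)
    degenerate = np.abs(triple) <= 1e-12 * np.maximum(la * lb * lc, 1e-300)
    return np.where(degenerate, 0.0, omega)


def tetra_solid_angle(apex, a, b, c) -> float:
    """Solid angle (steradians) subtended at *apex* by triangle *abc*."""
    return float(solid_angle_batch(np.asarray(apex, dtype=float),
                                   np.asarray(a, dtype=float),
                                   np.asarray(b, dtype=float),
                                   np.asarray(c, dtype=float)))


def _clamp_sa(sa: float | np.ndarray):
    if np.any(np.abs(sa) > 1.0 + SA_CONSISTENCY_TOL):
        raise ArithmeticError(
            f"solid-angle sum inconsistent: SA={sa} beyond ±(1+{SA_CONSISTENCY_TOL})")
    return np.clip(sa, -1.0, 1.0)


def interior_solid_angle(ac: AlphaComplex, vertex: int) -> float:
    """Ω_int: solid angle of the member tetrahedra incident at *vertex*."""
    tis = ac.incident_member_tetrahedra(vertex)
    if tis.size == 0:
        return 0.0
    pts = ac.points
    faces = []
    for ti in tis:
        tet = ac.triangulation.tetrahedra[ti]
        faces.append([v for v in tet if v != vertex])
    faces = np.asarray(faces, dtype=int)
    apex = np.broadcast_to(pts[vertex], (faces.shape[0], 3))
    return float(np.sum(solid_angle_batch(
        apex, pts[faces[:, 0]], pts[faces[:, 1]], pts[faces[:, 2]])))


def atom_solid_angle(ac: AlphaComplex, atom: int,
                     frame_index: int = 0) -> SolidAngleValue:
    """Curvature SA of one atom on one alpha complex.

    Surface atoms get ``SA = 1 − Ω_int/(2π)`` (clamped); singular atoms have
    Ω_int = 0 hence SA = 1; non-surface atoms (buried or hidden) get SA = 0
    with ``surface_flag = False``.
    """
    atom = int(atom)
    if atom in ac.singular_vertices:
        return SolidAngleValue(atom, frame_index, 1.0, True)
    if atom not in ac.surface_vertices:
        return SolidAngleValue(atom, frame_index, 0.0, False)
    sa = float(_clamp_sa(1.0 - interior_solid_angle(ac, atom) / TWO_PI))
    return SolidAngleValue(atom, frame_index, sa, True)


def frame_site_curvature(ac: AlphaComplex, site_atom_indices: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """(SA values, surface flags) for the given atoms on one complex.

    Vectorized over all (site atom, incident member tetrahedron) pairs.
    """
    site_atom_indices = np.asarray(site_atom_indices, dtype=int)
    n = site_atom_indices.size
    sa = np.zeros(n)
    flags = np.zeros(n, dtype=bool)
    surf = ac.surface_vertices
    sing = ac.singular_vertices
    apex_atoms, rows, tet_ids = [], [], []
    for j, atom in enumerate(site_atom_indices):
        atom = int(atom)
        if atom in sing:
            sa[j] = 1.0
            flags[j] = True
        elif atom in surf:
            flags[j] = True
            tis = ac.incident_member_tetrahedra(atom)
            apex_atoms.extend([atom] * tis.size)
            rows.extend([j] * tis.size)
            tet_ids.append(tis)
    if apex_atoms:
        pts = ac.points
        apex_idx = np.asarray(apex_atoms, dtype=int)
        rows = np.asarray(rows, dtype=int)
        tets = ac.triangulation.tetrahedra[np.concatenate(tet_ids)]
        faces = tets[tets != apex_idx[:, None]].reshape(-1, 3)
        omegas = solid_angle_batch(pts[apex_idx], pts[faces[:, 0]],
                                   pts[faces[:, 1]], pts[faces[:, 2]])
        omega_sum = np.zeros(n)
        np.add.at(omega_sum, rows, omegas)
        touched = np.zeros(n, dtype=bool)
        touched[rows] = True
        sa[touched] = _clamp_sa(1.0 - omega_sum[touched] / TWO_PI)
    return sa, flags


def trajectory_curvature(traj: Trajectory, site: BindingSite,
                         alpha: float = 0.0, *, jitter_seed: int = 0,
                         progress: bool = False) -> CurvatureProfile:
    """SA profile of the binding site over all trajectory frames.

    For each frame, the weighted alpha complex of the whole protein (all
    heavy atoms of the topology; the ligand is excluded) is rebuilt at that
    frame's coordinates and every binding-site atom is scored.
    """
    idx = np.asarray(site.atom_indices, dtype=int)
    if idx.size and idx.max() >= traj.topology.n_atoms:
        raise ValueError("binding-site atom index beyond topology")
    weights = traj.topology.weights
    F = traj.n_frames
    sa = np.zeros((F, idx.size))
    flags = np.zeros((F, idx.size), dtype=bool)
    for f in range(F):
        try:
            ac = build_alpha_complex(traj.frames[f], weights, alpha,
                                     jitter_seed=jitter_seed + f)
        except Exception as exc:
            raise RuntimeError(f"frame {f}: alpha complex failed: {exc}") from exc
        sa[f], flags[f] = frame_site_curvature(ac, idx)
        if progress and (f + 1) % 50 == 0:
            logger.info("curvature: frame %d/%d", f + 1, F)
    return CurvatureProfile(sa_matrix=sa, surface_flags=flags, site=site,
                            frame_spacing=traj.frame_spacing)


def structure_curvature(structure: Structure, site: BindingSite,
                        alpha: float = 0.0, *, jitter_seed: int = 0
                        ) -> CurvatureProfile:
    """Single-frame convenience: SA profile of a static structure."""
    traj = Trajectory(topology=structure,
                      frames=structure.positions[None, :, :],
                      frame_spacing=0.0)
    return trajectory_curvature(traj, site, alpha, jitter_seed=jitter_seed)
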