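"""Synthetic pocket structures, trajectories, and response cohorts.

Real inputs to this pipeline are modelled mutant structures relaxed by
molecular dynamics — neither of which is needed to exercise the geometry.
The generator builds the minimal object with the right geometric features: a
cubic-lattice slab of pseudo-atoms with a hemispherical cavity carved into
its top face (the "binding pocket"), plus a controllable number of
pocket-wall atoms displaced into the cavity (convex "knobs").  Trajectories
are the base structure plus per-frame Gaussian coordinate jitter — a
stand-in for thermal motion, not a dynamics engine.  Cohorts are two groups
of such pockets whose knob heights differ so that the group mean knob levels
differ by a target effect, with per-member variability.

Lattice constants: pseudo-atom radius 1.7 Å and spacing 3.4 Å.  With the
1.4 Å probe the weight is (1.7+1.4)² = 9.61 Å², and every lattice-cell
tetrahedron has squared circumradius 3·a²/4 = 8.67 Å² < 9.61 Å², so the slab
interior is solid at alpha = 0 (spacings above 2(r+probe)/√3 ≈ 3.58 Å would
leave no member tetrahedra and an all-singular slab).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import BindingSite, Structure, Trajectory, WeightedAtom, write_trajectory

__all__ = ["PocketSpec", "CohortSpec", "CohortMember", "make_pocket_structure",
           "jitter_trajectory", "make_cohort", "write_cohort"]

#: Knob placement of the common cohort scaffold (all members of a cohort
#: carry their knobs at the same pocket-wall positions, as point mutants of
#: one wild-type protein share its pocket).
SCAFFOLD_SEED = 0

#: Empirical sensitivity of the method-A knob level to knob height (per Å),
#: measured on the default lattice (6 knobs, alpha = 0, threshold 0.01,
#: 0.3 Å frame jitter, fixed scaffold) over the near-linear regime
#: h ∈ [1.6, 3.6] Å; used to
#: translate a target knob-level effect into a knob-height offset.
KNOB_HEIGHT_SLOPE = 0.0266


@dataclass(frozen=True)
class PocketSpec:
    """Geometry of one synthetic pocket.

    ``shape`` counts atoms per axis; the hemispherical cavity of radius
    ``pocket_radius`` is carved from the centre of the top (+z) face;
    ``knob_count`` cavity-wall atoms are displaced ``knob_height`` Å toward
    the cavity centre.  All lengths in Å.
    """

    shape: tuple[int, int, int] = (8, 8, 4)
    spacing: float = 3.4
    atom_radius: float = 1.7
    probe_radius: float = 1.4
    pocket_radius: float = 6.0
    knob_count: int = 0
    knob_height: float = 3.2
    seed: int = 0

    def __post_init__(self) -> None:
        half_width = (min(self.shape[0], self.shape[1]) - 1) * self.spacing / 2.0
        if not self.pocket_radius < half_width:
            raise ValueError("pocket_radius must be smaller than the slab half-width")
        if self.knob_count < 0 or self.knob_height < 0:
            raise ValueError("knob_count and knob_height must be non-negative")


def _pick_spread(rng: np.random.Generator, pos: np.ndarray,
                 candidates: np.ndarray, k: int, min_sep: float) -> list[int]:
    """Seeded greedy pick of k candidates, preferring pairwise separation
    ≥ min_sep (knobs shield each other when adjacent); falls back to the
    remaining candidates if the separated set is exhausted."""
    if k == 0:
        return []
    order = rng.permutation(len(candidates))
    chosen: list[int] = []
    for j in order:
        i = int(candidates[j])
        if all(np.linalg.norm(pos[i] - pos[c]) >= min_sep for c in chosen):
            chosen.append(i)
            if len(chosen) == k:
                return chosen
    for j in order:
        i = int(candidates[j])
        if i not in chosen:
            chosen.append(i)
            if len(chosen) == k:
                break
    return chosen


def make_pocket_structure(spec: PocketSpec) -> tuple[Structure, BindingSite]:
    """Build the slab-with-pocket structure and its cavity-lining site.

    Deterministic given the spec (knob positions are drawn with the spec's
    seed).  The binding site contains every surviving atom within one lattice
    spacing of the cavity surface — the pocket lining — including the knobs.
    """
    nx, ny, nz = spec.shape
    a = spec.spacing
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    pos = np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()]).astype(float) * a
    center = np.array([(nx - 1) * a / 2.0, (ny - 1) * a / 2.0, (nz - 1) * a])
    dist = np.linalg.norm(pos - center, axis=1)
    keep = dist >= spec.pocket_radius
    pos = pos[keep]
    dist = dist[keep]
    lining = np.nonzero(dist <= spec.pocket_radius + a)[0]
    if lining.size == 0:
        raise ValueError("pocket spec leaves no cavity-lining atoms")
    # knobs: wall/floor lining atoms (not the top rim), displaced toward the centre
    z_top = (nz - 1) * a
    wall = lining[pos[lining, 2] <= z_top - a / 2.0]
    if spec.knob_count > wall.size:
        raise ValueError(f"knob_count {spec.knob_count} exceeds the "
                         f"{wall.size} available pocket-wall positions")
    rng = np.random.default_rng(spec.seed)
    knobs = _pick_spread(rng, pos, wall, spec.knob_count, 1.5 * a)
    for i in knobs:
        u = center - pos[i]
        pos[i] = pos[i] + spec.knob_height * u / np.linalg.norm(u)
    w = (spec.atom_radius + spec.probe_radius) ** 2
    atoms = [WeightedAtom(serial=i + 1, name="C", element="C", residue_name="LAT",
                          residue_id=i + 1, chain="A", position=pos[i].copy(),
                          radius=spec.atom_radius, weight=w)
             for i in range(pos.shape[0])]
    structure = Structure(atoms=atoms, label=f"pocket_seed{spec.seed}")
    site = BindingSite(
        residue_keys=[("A", int(i) + 1) for i in lining],
        atom_indices=np.asarray(lining, dtype=int))
    return structure, site


def jitter_trajectory(structure: Structure, n_frames: int, sd: float,
                      seed: int, frame_spacing: float = 10.0) -> Trajectory:
    """Gaussian-jitter trajectory: frame 0 is the base structure, frames
    1..F−1 add independent N(0, sd) noise per coordinate (Å)."""
    if sd < 0:
        raise ValueError("sd must be ≥ 0")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    base = structure.positions
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    if n_frames > 1 and sd > 0:
        frames[1:] += rng.normal(0.0, sd, size=(n_frames - 1,) + base.shape)
    return Trajectory(topology=structure, frames=frames, frame_spacing=frame_spacing)


@dataclass(frozen=True)
class CohortSpec:
    """A two-group cohort of synthetic pocket trajectories.

    ``effect`` is the target difference in group mean knob level
    (No-response − Response, method A at the default threshold);
    ``knob_level_sd`` the target per-member knob-level spread within a
    group, realized as knob-height jitter.  Defaults model a 30-member
    cohort whose groups are separated by five within-group SDs.
    """

    n_response: int = 16
    n_noresponse: int = 14
    effect: float = 0.05
    knob_level_sd: float = 0.010
    frame_noise_sd: float = 0.3
    n_frames: int = 50
    frame_spacing: float = 10.0
    seed: int = 0
    base_knob_count: int = 6
    base_knob_height: float = 1.6
    pocket: PocketSpec = field(default_factory=PocketSpec)

    def __post_init__(self) -> None:
        if self.n_response < 1 or self.n_noresponse < 1:
            raise ValueError("both groups need at least one member")


@dataclass
class CohortMember:
    mutant_id: str
    trajectory: Trajectory
    site: BindingSite
    rl: int


def make_cohort(spec: CohortSpec) -> list[CohortMember]:
    """Generate the cohort: Response members (RL 1, 2 round-robin) with low
    knobs, No-response members (RL 3, 4) with knobs raised by
    ``effect / KNOB_HEIGHT_SLOPE`` Å.

    All members share one fixed knob placement (``SCAFFOLD_SEED``) — the
    cohort's common scaffold, mirroring how real mutant cohorts share one
    wild-type pocket; the planted signal is the group knob-height offset and
    the per-member variability is knob-height jitter
    (``knob_level_sd / KNOB_HEIGHT_SLOPE`` Å) plus the thermal frame noise.
    Per-member seeds derive from the base seed; the whole cohort is a pure
    function of the spec."""
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_response + spec.n_noresponse)
    height_sd = spec.knob_level_sd / KNOB_HEIGHT_SLOPE
    delta_h = spec.effect / KNOB_HEIGHT_SLOPE
    members: list[CohortMember] = []
    k = 0
    for group, n in (("R", spec.n_response), ("N", spec.n_noresponse)):
        for j in range(n):
            child = children[k]
            seeds = child.generate_state(2) % (2 ** 31)
            rng = np.random.default_rng(int(seeds[0]))
            h = spec.base_knob_height + (delta_h if group == "N" else 0.0)
            h = float(np.clip(h + rng.normal(0.0, height_sd), 0.05, None))
            pocket = PocketSpec(
                shape=spec.pocket.shape, spacing=spec.pocket.spacing,
                atom_radius=spec.pocket.atom_radius,
                probe_radius=spec.pocket.probe_radius,
                pocket_radius=spec.pocket.pocket_radius,
                knob_count=spec.base_knob_count, knob_height=h,
                seed=SCAFFOLD_SEED)
            structure, site = make_pocket_structure(pocket)
            rl = (1, 2)[j % 2] if group == "R" else (3, 4)[j % 2]
            mid = f"{'resp' if group == 'R' else 'nores'}_{j:02d}"
            structure.label = mid
            traj = jitter_trajectory(structure, spec.n_frames,
                                     spec.frame_noise_sd, int(seeds[1]),
                                     spec.frame_spacing)
            members.append(CohortMember(mutant_id=mid, trajectory=traj,
                                        site=site, rl=rl))
            k += 1
    return members


def write_cohort(members: list[CohortMember], outdir: str | Path) -> Path:
    """Write the cohort as files: one multi-model PDB per member, a cohort
    CSV (mutant_id, rl), and the shared site residue list (chain,
    residue_id) — so the file-based pipeline runs exactly as with real data,
    where one reference site is reused for every mutant."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "cohort.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["mutant_id", "rl"])
        for m in members:
            wr.writerow([m.mutant_id, m.rl])
    with open(outdir / "site_residues.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["chain", "residue_id"])
        for chain, rid in members[0].site.residue_keys:
            wr.writerow([chain, rid])
    for m in members:
        write_trajectory(m.trajectory, outdir / f"{m.mutant_id}.pdb")
    return outdir
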