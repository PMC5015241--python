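"""PDB I/O, weighting, and binding-site selection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from alphapocket import (BindingSite, PDBFormatError, Structure, Trajectory,
                         jitter_trajectory, read_pdb, read_trajectory,
                         select_binding_site, vdw_radius, write_pdb,
                         write_trajectory)
from conftest import make_atom, structure_from_points


def pdb_atom_line(serial, name, res, chain, resid, x, y, z, element,
                  record="ATOM"):
    return (f"{record:<6}{serial:>5} {name:<4}{res:>4} {chain}{resid:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{element:>2}\n")


def test_read_pdb_assigns_bondi_radii_and_probe_weights(tmp_path):
    """Three heavy atoms get Bondi radii and (r + 1.4)² weights."""
    path = tmp_path / "three.pdb"
    path.write_text(
        pdb_atom_line(1, "C", "ALA", "A", 1, 0.0, 0.0, 0.0, "C")
        + pdb_atom_line(2, "N", "ALA", "A", 1, 1.5, 0.0, 0.0, "N")
        + pdb_atom_line(3, "O", "ALA", "A", 1, 0.0, 1.5, 0.0, "O"))
    s = read_pdb(path)
    assert s.n_atoms == 3
    np.testing.assert_allclose(s.radii, [1.70, 1.55, 1.52])
    np.testing.assert_allclose(s.weights, [(r + 1.4) ** 2 for r in s.radii])
    assert s.atoms[1].element == "N" and s.atoms[1].residue_id == 1


def test_read_pdb_nonnumeric_coordinate_is_format_error_with_line(tmp_path):
    path = tmp_path / "bad.pdb"
    good = pdb_atom_line(1, "C", "ALA", "A", 1, 0.0, 0.0, 0.0, "C")
    bad = good.replace("   0.000", "  abc   ", 1)
    path.write_text(good + bad)
    with pytest.raises(PDBFormatError, match="line 2"):
        read_pdb(path)


def test_read_pdb_drops_hydrogens_and_waters(tmp_path):
    path = tmp_path / "mixed.pdb"
    path.write_text(
        pdb_atom_line(1, "C", "ALA", "A", 1, 0.0, 0.0, 0.0, "C")
        + pdb_atom_line(2, "H", "ALA", "A", 1, 0.5, 0.0, 0.0, "H")
        + pdb_atom_line(3, "O", "HOH", "A", 99, 5.0, 5.0, 5.0, "O",
                        record="HETATM"))
    s = read_pdb(path)
    assert [a.element for a in s.atoms] == ["C"]


def test_read_pdb_routes_ligand_hetatm_records(tmp_path):
    path = tmp_path / "lig.pdb"
    path.write_text(
        pdb_atom_line(1, "C", "ALA", "A", 1, 0.0, 0.0, 0.0, "C")
        + pdb_atom_line(2, "C1", "DRG", "A", 90, 3.0, 0.0, 0.0, "C",
                        record="HETATM"))
    s = read_pdb(path, ligand_resname="DRG")
    assert s.n_atoms == 1 and len(s.ligand_atoms) == 1
    assert s.ligand_atoms[0].residue_name == "DRG"


def test_multimodel_read_selects_requested_model(tmp_path):
    """model=3 of a 5-model file matches an independent line-by-line parse."""
    base = structure_from_points([[0, 0, 0], [2, 0, 0], [0, 2, 0]])
    traj = jitter_trajectory(base, 5, 0.5, seed=11)
    path = tmp_path / "multi.pdb"
    write_trajectory(traj, path)

    # independent parse: coordinates of the third MODEL block
    coords, in_model = [], False
    for line in path.read_text().splitlines():
        if line.startswith("MODEL") and line.split()[1] == "3":
            in_model = True
        elif line.startswith("ENDMDL"):
            in_model = False
        elif in_model and line.startswith(("ATOM", "HETATM")):
            coords.append([float(line[30:38]), float(line[38:46]),
                           float(line[46:54])])
    s3 = read_pdb(path, model=3)
    np.testing.assert_allclose(s3.positions, np.array(coords), atol=5e-4)


def test_structure_roundtrip_preserves_order_and_3decimals(tmp_path):
    rng = np.random.default_rng(12)
    s = structure_from_points(rng.normal(0, 5, (9, 3)))
    path = tmp_path / "s.pdb"
    write_pdb(s, path)
    back = read_pdb(path)
    assert [a.serial for a in back.atoms] == [a.serial for a in s.atoms]
    np.testing.assert_allclose(back.positions, s.positions, atol=5e-4)


def test_trajectory_roundtrip_preserves_order_and_3decimals(tmp_path):
    base = structure_from_points(np.random.default_rng(4).normal(0, 3, (7, 3)))
    traj = jitter_trajectory(base, 3, 0.4, seed=2)
    path = tmp_path / "t.pdb"
    write_trajectory(traj, path)
    back = read_trajectory(path, frame_spacing=10.0)
    assert back.n_frames == 3
    assert [a.serial for a in back.topology.atoms] == list(range(1, 8))
    np.testing.assert_allclose(back.frames, traj.frames, atol=5e-4)


@given(st.integers(min_value=1, max_value=12))
def test_frame_count_equals_model_block_count(tmp_path_factory, n_models):
    base = structure_from_points([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
    traj = jitter_trajectory(base, n_models, 0.2, seed=n_models)
    path = tmp_path_factory.mktemp("frames") / "t.pdb"
    write_trajectory(traj, path)
    text = path.read_text()
    back = read_trajectory(path)
    assert back.n_frames == n_models
    if n_models > 1:  # a 1-frame file is written without MODEL records
        assert text.count("ENDMDL") == n_models


def test_inconsistent_model_atom_counts_error_names_model(tmp_path):
    lines = ["MODEL     1\n"]
    for i in range(5):
        lines.append(pdb_atom_line(i + 1, "C", "ALA", "A", i + 1, i, 0, 0, "C"))
    lines += ["ENDMDL\n", "MODEL     2\n"]
    for i in range(4):
        lines.append(pdb_atom_line(i + 1, "C", "ALA", "A", i + 1, i, 0, 1, "C"))
    lines += ["ENDMDL\n"]
    (tmp_path / "bad.pdb").write_text("".join(lines))
    with pytest.raises(PDBFormatError, match="model 2"):
        read_trajectory(tmp_path / "bad.pdb")


def test_single_model_file_is_one_frame(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(pdb_atom_line(1, "C", "ALA", "A", 1, 0, 0, 0, "C")
                    + pdb_atom_line(2, "C", "ALA", "A", 2, 3, 0, 0, "C"))
    assert read_trajectory(path).n_frames == 1


def test_unknown_element_uses_fallback_and_none_errors(tmp_path):
    path = tmp_path / "odd.pdb"
    path.write_text(pdb_atom_line(1, "X", "UNK", "A", 1, 0, 0, 0, "XX"))
    assert read_pdb(path).radii[0] == 1.7
    with pytest.raises(KeyError):
        read_pdb(path, fallback_radius=None)
    assert vdw_radius("ZZ", fallback=2.0) == 2.0


class TestBindingSite:
    def two_residue_structure(self):
        """Residue 1 at ~3 Å from the ligand, residue 2 at ~12 Å."""
        atoms = [make_atom(1, 3.0, 0, 0, residue_id=1),
                 make_atom(2, 4.5, 0, 0, residue_id=1),
                 make_atom(3, 12.0, 0, 0, residue_id=2),
                 make_atom(4, 13.5, 0, 0, residue_id=2)]
        ligand = [make_atom(10, 0.0, 0, 0, residue_id=50, residue_name="DRG")]
        return Structure(atoms=atoms, ligand_atoms=ligand)

    def test_cutoff_selects_whole_near_residue(self):
        s = self.two_residue_structure()
        site = select_binding_site(s, "ligand-cutoff", cutoff=5.0)
        assert site.n_residues == 1 and site.n_atoms == 2
        assert list(site.atom_indices) == [0, 1]

    def test_empty_selection_errors(self):
        s = self.two_residue_structure()
        with pytest.raises(ValueError, match="cutoff"):
            select_binding_site(s, "ligand-cutoff", cutoff=1.0)

    def test_residue_list_mode_verbatim(self):
        s = self.two_residue_structure()
        site = select_binding_site(s, "residue-list", residues=[("A", 2)])
        assert list(site.atom_indices) == [2, 3]

    def test_cutoff_matches_brute_force_scan(self):
        """Random 10-residue structure vs an independent double loop."""
        rng = np.random.default_rng(7)
        atoms = []
        serial = 0
        for resid in range(1, 11):
            center = rng.uniform(-8, 8, 3)
            for _ in range(rng.integers(2, 5)):
                serial += 1
                p = center + rng.normal(0, 1.0, 3)
                atoms.append(make_atom(serial, *p, residue_id=resid))
        ligand = [make_atom(900 + i, *rng.uniform(-2, 2, 3), residue_id=99,
                            residue_name="DRG") for i in range(3)]
        s = Structure(atoms=atoms, ligand_atoms=ligand)
        site = select_binding_site(s, "ligand-cutoff", cutoff=5.0)

        hit_residues = set()
        for a in s.atoms:
            for la in s.ligand_atoms:
                if np.linalg.norm(a.position - la.position) <= 5.0:
                    hit_residues.add((a.chain, a.residue_id))
        expected = [i for i, a in enumerate(s.atoms)
                    if (a.chain, a.residue_id) in hit_residues]
        assert list(site.atom_indices) == expected
        assert site.n_residues == len(hit_residues)

    def test_site_resolves_across_structures_by_residue_key(self):
        """The same residue keys select the same atom count on any frame."""
        s = self.two_residue_structure()
        site = select_binding_site(s, "ligand-cutoff", cutoff=5.0)
        shuffled = Structure(atoms=[s.atoms[i] for i in (2, 0, 3, 1)])
        resolved = site.resolve(shuffled)
        assert resolved.n_atoms == site.n_atoms
        assert {shuffled.atoms[i].residue_id for i in resolved.atom_indices} == {1}


def test_trajectory_validates_atom_count():
    base = structure_from_points([[0, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError):
        Trajectory(topology=base, frames=np.zeros((2, 3, 3)))


def test_structure_rejects_duplicate_serials():
    with pytest.raises(ValueError):
        Structure(atoms=[make_atom(1, 0, 0, 0), make_atom(1, 3, 0, 0)])


def test_dataframe_export_flags_site(tmp_path):
    s = structure_from_points([[0, 0, 0], [3, 0, 0], [0, 3, 0]])
    site = BindingSite(residue_keys=[("A", 1)], atom_indices=np.array([0]))
    df = s.to_dataframe(site)
    assert df["in_site"].tolist() == [True, False, False]
    assert set(df.columns) >= {"serial", "element", "radius", "weight"}
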