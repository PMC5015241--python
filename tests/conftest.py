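"""Shared fixtures and independent geometric oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from alphapocket import (PocketSpec, Structure, WeightedAtom,
                         make_pocket_structure)

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_atom(serial, x, y, z, element="C", residue_id=None, chain="A",
              radius=1.7, probe=1.4, name=None, residue_name="LAT"):
    return WeightedAtom(
        serial=serial, name=name or element, element=element,
        residue_name=residue_name,
        residue_id=residue_id if residue_id is not None else serial,
        chain=chain, position=np.array([x, y, z], dtype=float),
        radius=radius, weight=(radius + probe) ** 2)


def structure_from_points(points, radius=1.7, probe=1.4) -> Structure:
    atoms = [make_atom(i + 1, *p, radius=radius, probe=probe)
             for i, p in enumerate(np.asarray(points, dtype=float))]
    return Structure(atoms=atoms)


def random_blob(rng, n=18, scale=2.5, rmin=1.2, rmax=2.0, probe=1.4):
    """A random compact cluster of weighted atoms (general position)."""
    points = rng.normal(0.0, scale, size=(n, 3))
    radii = rng.uniform(rmin, rmax, size=n)
    weights = (radii + probe) ** 2
    return points, weights


def mc_solid_angle(ac, atom, n_samples=100_000, seed=0, eps=1e-3):
    """Monte Carlo curvature oracle, independent of the analytic formula.

    Samples uniform directions on a tiny sphere around the atom and counts
    the fraction of sample points contained in ANY member tetrahedron of the
    alpha complex: Ω_int ≈ 4π·fraction, so SA ≈ 1 − 2·fraction.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_samples, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = ac.points[atom] + eps * u
    inside = np.zeros(n_samples, dtype=bool)
    for tet in ac.member_tetrahedra:
        a = ac.points[tet[0]]
        m = np.stack([ac.points[tet[1]] - a, ac.points[tet[2]] - a,
                      ac.points[tet[3]] - a])
        try:
            lam = np.linalg.solve(m.T, (pts - a).T).T
        except np.linalg.LinAlgError:
            continue
        tol = 1e-9
        inside |= (np.all(lam >= -tol, axis=1) & (lam.sum(axis=1) <= 1 + tol))
        if inside.all():
            break
    return 1.0 - 2.0 * inside.mean()


@pytest.fixture(scope="session")
def pocket_no_knobs():
    return make_pocket_structure(PocketSpec(knob_count=0, seed=0))


@pytest.fixture(scope="session")
def pocket_with_knobs():
    return make_pocket_structure(PocketSpec(knob_count=5, knob_height=3.2, seed=3))
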