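"""H-bond detection, Shrake–Rupley SASA against closed forms, disulfide
distances and the Bdamage packing-density metric."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_atom
from dloss.context import (compute_bdamage, correlate_context,
                           disulfide_distance, find_tyr_hbonds,
                           relative_bdamage_change, solvent_accessibility,
                           tyr_hbond_partition, tyr_ring_areas)
from dloss.structures import Structure, UnitCell

CELL = UnitCell(60.0, 60.0, 60.0)


def pair_structure(distance):
    atoms = [make_atom(1, "OH", "TYR", 1, "O", (10.0, 10.0, 10.0)),
             make_atom(2, "OE1", "GLU", 2, "O", (10.0 + distance, 10.0, 10.0))]
    return Structure(atoms, CELL)


@pytest.mark.parametrize("distance,n_pairs", [
    (3.5, 1),
    (4.0, 0),      # cutoff is strict: "under 4 Å"
    (4.5, 0),
])
def test_hbond_cutoff_is_strict(distance, n_pairs):
    assert len(find_tyr_hbonds(pair_structure(distance))) == n_pairs


def test_hbond_empty_without_acidic_residues():
    s = Structure([make_atom(1, "OH", "TYR", 1, "O")], CELL)
    assert find_tyr_hbonds(s) == []


def test_hbond_partition_is_disjoint_and_exhaustive(toy_structure):
    bonded, free = tyr_hbond_partition(toy_structure)
    assert bonded and free
    assert bonded.isdisjoint(free)
    all_tyr = {(a.chain_id, a.residue_number) for a in toy_structure.atoms
               if a.residue_name == "TYR" and a.name == "OH"}
    assert bonded | free == all_tyr


# -------------------------------------------------------------- SASA

def test_isolated_sphere_matches_analytic_area():
    s = Structure([make_atom(1, "CA", "GLY", 1, "C", (30, 30, 30))], CELL)
    area = solvent_accessibility(s).iloc[0]
    analytic = 4 * np.pi * (1.70 + 1.4) ** 2
    assert abs(area - analytic) / analytic < 0.01


def test_distant_atoms_do_not_occlude():
    atoms = [make_atom(1, "CA", "GLY", 1, "C", (5, 5, 5)),
             make_atom(2, "CB", "ALA", 2, "C", (55, 55, 55))]
    areas = solvent_accessibility(Structure(atoms, CELL))
    analytic = 4 * np.pi * (1.70 + 1.4) ** 2
    np.testing.assert_allclose(areas.to_numpy(), analytic, rtol=0.01)


def spherical_cap_two_sphere_area(R, d):
    """Accessible area of one of two equal spheres (radius R, centres d apart)."""
    x = d / 2.0
    return 4 * np.pi * R**2 - 2 * np.pi * R * (R - x)


@pytest.mark.parametrize("d", [2.0, 3.0, 4.0, 5.0])
def test_two_overlapping_spheres_match_cap_formula(d):
    atoms = [make_atom(1, "CA", "GLY", 1, "C", (30, 30, 30)),
             make_atom(2, "CB", "ALA", 2, "C", (30 + d, 30, 30))]
    areas = solvent_accessibility(Structure(atoms, CELL))
    expected = spherical_cap_two_sphere_area(1.70 + 1.4, d)
    np.testing.assert_allclose(areas.to_numpy(), expected, rtol=0.015)


def test_occlusion_is_monotone_in_approach():
    last = np.inf
    for d in (6.5, 5.0, 4.0, 3.0, 2.0):
        atoms = [make_atom(1, "CA", "GLY", 1, "C", (30, 30, 30)),
                 make_atom(2, "CB", "ALA", 2, "C", (30 + d, 30, 30))]
        area = solvent_accessibility(Structure(atoms, CELL)).iloc[0]
        assert area <= last + 1e-9
        last = area


def test_unknown_element_radius_raises():
    s = Structure([make_atom(1, "FE", "HEM", 1, "FE", (30, 30, 30))], CELL)
    with pytest.raises(ValueError, match="FE"):
        solvent_accessibility(s)


def test_carboxylate_removal_increases_neighbouring_tyr_ring_area(toy_structure):
    with_cbx = solvent_accessibility(toy_structure)
    without = solvent_accessibility(toy_structure, remove_carboxylates=True)
    ring_with = tyr_ring_areas(with_cbx, toy_structure)
    ring_without = tyr_ring_areas(without, toy_structure)
    bonded, _ = tyr_hbond_partition(toy_structure)
    gain = (ring_without - ring_with)[sorted(bonded)]
    assert (gain > 0).all()    # removing the adjacent CO2 exposes the ring
    # carboxylate atoms are absent from the reduced table (OE2/OD2 are unique
    # to Glu/Asp; GLN's OE1 must survive)
    names_left = {idx[2] for idx in without.index}
    assert "OE2" not in names_left and "OD2" not in names_left
    assert "OE1" in names_left   # the GLN amide oxygen remains


# -------------------------------------------------------------- disulfides

def test_disulfide_midpoint_distance():
    atoms = [make_atom(1, "SG", "CYS", 1, "S", (10, 10, 10)),
             make_atom(2, "SG", "CYS", 2, "S", (12.0, 10, 10)),
             make_atom(3, "OH", "TYR", 3, "O", (11.0, 16.0, 10.0))]
    s = Structure(atoms, CELL)
    dist = disulfide_distance(s)
    assert dist[("A", 3)] == pytest.approx(6.0)


def test_sg_pair_beyond_cutoff_is_not_a_disulfide():
    atoms = [make_atom(1, "SG", "CYS", 1, "S", (10, 10, 10)),
             make_atom(2, "SG", "CYS", 2, "S", (13.5, 10, 10)),
             make_atom(3, "OH", "TYR", 3, "O", (11, 16, 10))]
    assert disulfide_distance(Structure(atoms, CELL)).empty


def test_multiple_disulfides_take_minimum_and_modes_differ():
    atoms = [make_atom(1, "SG", "CYS", 1, "S", (10, 10, 10)),
             make_atom(2, "SG", "CYS", 2, "S", (12, 10, 10)),
             make_atom(3, "SG", "CYS", 3, "S", (40, 40, 40)),
             make_atom(4, "SG", "CYS", 4, "S", (42, 40, 40)),
             make_atom(5, "OH", "TYR", 5, "O", (20, 10, 10))]
    s = Structure(atoms, CELL)
    mid = disulfide_distance(s)[("A", 5)]
    # brute force over both midpoints
    mids = [np.array([11.0, 10, 10]), np.array([41.0, 40, 40])]
    expected = min(np.linalg.norm(np.array([20.0, 10, 10]) - m) for m in mids)
    assert mid == pytest.approx(expected)
    near_s = disulfide_distance(s, mode="nearest_s")[("A", 5)]
    assert near_s == pytest.approx(8.0)   # nearest SG at (12,10,10)


# -------------------------------------------------------------- Bdamage

def test_uniform_b_gives_bdamage_one(toy_structure):
    uniform = toy_structure.copy()
    for a in uniform.atoms:
        a.b_factor = 15.0
    rec = compute_bdamage(uniform)
    np.testing.assert_array_equal(rec["bdamage"].to_numpy(), 1.0)


def test_relative_change_formula():
    base = pd.DataFrame({"chain": ["A"], "residue_number": [1],
                         "residue_name": ["TYR"], "atom_name": ["OH"],
                         "packing_density": [5], "bin_id": [0],
                         "bdamage": [1.2]})
    later = base.copy()
    later["bdamage"] = [1.8]
    change = relative_bdamage_change(base, later)
    assert change.iloc[0] == pytest.approx(0.5)


def test_packing_density_matches_pairwise_oracle(toy_structure):
    rec = compute_bdamage(toy_structure, r_pd=7.0)
    atoms = toy_structure.heavy_atoms()
    cell = toy_structure.cell
    rng = np.random.default_rng(3)
    for i in rng.choice(len(atoms), size=12, replace=False):
        count = 0
        for j, other in enumerate(atoms):
            if i == j:
                continue
            d = cell.fractionalize(atoms[i].position - other.position)
            d -= np.round(d)
            if np.linalg.norm(cell.orthogonalize(d)) <= 7.0:
                count += 1
        assert rec["packing_density"].iloc[i] == count


def test_bdamage_invariant_under_rigid_motion(toy_structure):
    # non-periodic mode: an isolated molecule may be rotated/translated freely
    rec0 = compute_bdamage(toy_structure, periodic=False)
    moved = toy_structure.copy()
    theta = np.deg2rad(25.0)
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0],
                  [0, 0, 1]])
    for a in moved.atoms:
        a.position = R @ a.position + np.array([1.0, -2.0, 3.0])
    rec1 = compute_bdamage(moved, periodic=False)
    np.testing.assert_allclose(rec0["bdamage"], rec1["bdamage"], rtol=1e-10)
    np.testing.assert_array_equal(rec0["packing_density"],
                                  rec1["packing_density"])


# -------------------------------------------------------------- correlates

def dloss_table_for_tyr(n_tyr, values, dataset="d2"):
    rows = []
    for i, v in enumerate(values, start=1):
        rows.append(("A", i, "TYR", "OH", dataset, 2.0, v, v, v))
    return pd.DataFrame(rows, columns=[
        "chain", "residue_number", "residue_name", "atom_name", "dataset",
        "dose_MGy", "dloss_raw", "dloss_sigma", "dloss_ca_norm"])


def test_affine_covariate_gives_r2_one():
    vals = np.linspace(0.1, 1.0, 10)
    table = dloss_table_for_tyr(10, vals)
    cov = pd.Series({("A", i + 1): 3.0 * v - 1.0 for i, v in enumerate(vals)})
    res = correlate_context(table, cov)
    assert res["d2"].statistic == pytest.approx(1.0)


def test_independent_covariate_gives_low_r2():
    rng = np.random.default_rng(31)
    vals = rng.normal(size=30)
    table = dloss_table_for_tyr(30, vals)
    cov = pd.Series({("A", i + 1): rng.normal() for i in range(30)})
    assert correlate_context(table, cov)["d2"].statistic < 0.1


def test_too_few_tyr_skipped():
    vals = np.linspace(0.1, 0.7, 7)
    table = dloss_table_for_tyr(7, vals)
    cov = pd.Series({("A", i + 1): v for i, v in enumerate(vals)})
    assert correlate_context(table, cov) == {}
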