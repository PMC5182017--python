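"""Reflection I/O, amplitude scaling, difference-map synthesis and the
FFT / direct-summation equivalence that underpins every downstream number."""

import numpy as np
import pytest

from conftest import make_atom
from dloss.reflections import (ReflectionSet, combine_datasets, difference_map,
                               direct_summation_map, hemisphere_indices,
                               minimum_grid_shape, read_ccp4_map,
                               read_reflections, scale_amplitudes,
                               scaling_factor, structure_factors_from_model,
                               write_ccp4_map, write_reflections)
from dloss.structures import Structure, UnitCell


def random_reflections(seed, n=20, cell=None, n_datasets=2, dmin=2.0):
    rng = np.random.default_rng(seed)
    cell = cell or UnitCell(10.0, 10.0, 10.0)
    pool = hemisphere_indices(cell, dmin)
    pick = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    hkl = pool[np.sort(pick)]
    amps = rng.uniform(0.1, 5.0, size=(n_datasets, len(hkl)))
    phases = rng.uniform(0.0, 360.0, size=len(hkl))
    return ReflectionSet(hkl, amps, phases, dmin=dmin, cell=cell)


# -------------------------------------------------------------- text I/O

def test_read_reflections_round_trip(tmp_path):
    refl = random_reflections(0, n=15, n_datasets=3)
    path = tmp_path / "refl.tsv"
    write_reflections(refl, path)
    back = read_reflections(path)
    np.testing.assert_array_equal(back.miller_indices, refl.miller_indices)
    np.testing.assert_allclose(back.amplitudes, refl.amplitudes, rtol=1e-6)
    np.testing.assert_allclose(back.phases_first, refl.phases_first, rtol=1e-6)
    assert back.n_datasets == 3


def test_read_reflections_drops_incomplete_rows(tmp_path):
    path = tmp_path / "r.tsv"
    path.write_text("# cell: 10 10 10 90 90 90\n# dmin: 2.0\n"
                    "H K L F1 F2 PHI1\n"
                    "1 0 0 1.0 2.0 0.0\n"
                    "0 1 0 1.5 nan 90.0\n"
                    "0 0 1 2.0 1.0 180.0\n")
    refl = read_reflections(path)
    assert refl.n_reflections == 2


@pytest.mark.parametrize("body,err", [
    ("1 0 0 1.0 0.0\n1 0 0 2.0 0.0\n", "duplicate"),
    ("1 0 0 -1.0 0.0\n", "negative"),
])
def test_read_reflections_rejects_bad_rows(tmp_path, body, err):
    path = tmp_path / "bad.tsv"
    path.write_text("# cell: 10 10 10 90 90 90\nH K L F1 PHI1\n" + body)
    with pytest.raises(ValueError, match=err):
        read_reflections(path)


# -------------------------------------------------------------- scaling

def test_scaling_closed_form():
    f1 = np.array([1.0, 2.0, 3.0])
    assert scaling_factor(f1, 2.0 * f1) == pytest.approx(0.5)
    assert scaling_factor(f1, f1) == pytest.approx(1.0)


def test_scaling_matches_grid_search_oracle():
    rng = np.random.default_rng(7)
    f1 = rng.uniform(0.5, 4.0, size=200)
    fn = rng.uniform(0.5, 4.0, size=200)
    k = scaling_factor(f1, fn)
    ks = np.linspace(k - 0.5, k + 0.5, 200001)
    loss = ((ks[:, None] * fn[None, :] - f1[None, :]) ** 2).sum(axis=1)
    assert abs(ks[np.argmin(loss)] - k) < 1e-5   # grid resolution 5e-6
    # analytic optimality: derivative zero
    assert np.dot(k * fn - f1, fn) == pytest.approx(0.0, abs=1e-8)


def test_scale_amplitudes_applies_to_requested_dataset():
    refl = random_reflections(1)
    refl.amplitudes[1] = 2.0 * refl.amplitudes[0]
    scaled = scale_amplitudes(refl, 2)
    np.testing.assert_allclose(scaled.amplitudes[1], refl.amplitudes[0])
    with pytest.raises(ValueError):
        scale_amplitudes(refl, 1)


# -------------------------------------------------------------- maps

def test_zero_difference_gives_zero_map():
    refl = random_reflections(2)
    refl.amplitudes[1] = refl.amplitudes[0].copy()
    m = difference_map(refl, 2, (16, 16, 16))
    assert np.abs(m.values).max() < 1e-14
    assert m.sigma < 1e-14


def test_single_reflection_map_is_cosine():
    cell = UnitCell(10.0, 10.0, 10.0)
    refl = ReflectionSet(np.array([[1, 0, 0]]), np.array([[2.0], [1.0]]),
                         np.array([0.0]), dmin=5.0, cell=cell)
    m = difference_map(refl, 2, (8, 8, 8), scale=False)
    x = np.arange(8) / 8.0
    expected = -(2.0 / cell.volume) * np.cos(2 * np.pi * x)   # ΔF = −1
    np.testing.assert_allclose(m.values[:, 0, 0], expected, atol=1e-12)
    # constant along the other axes
    assert np.ptp(m.values, axis=1).max() < 1e-12


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("cell", [UnitCell(10, 10, 10),
                                  UnitCell(11, 13, 9, 85, 95, 102)])
def test_fft_map_equals_direct_summation(seed, cell):
    refl = random_reflections(seed, n=20, cell=cell)
    shape = minimum_grid_shape(cell, refl.dmin)
    fft = difference_map(refl, 2, shape)
    direct = direct_summation_map(refl, 2, shape)
    scale = np.abs(direct.values).max()
    assert np.abs(fft.values - direct.values).max() <= 1e-6 * scale


def test_difference_map_linearity_and_negation():
    refl = random_reflections(3, n_datasets=1)
    f1 = refl.amplitudes[0]
    rng = np.random.default_rng(30)
    da = rng.uniform(-0.05, 0.05, size=f1.size)
    db = rng.uniform(-0.05, 0.05, size=f1.size)
    shape = (12, 12, 12)

    def map_of(delta):
        r = combine_datasets(refl, [f1 + delta])
        return difference_map(r, 2, shape, scale=False).values

    np.testing.assert_allclose(map_of(da + db), map_of(da) + map_of(db),
                               atol=1e-12)
    np.testing.assert_array_equal(map_of(-da), -map_of(da))


def test_map_mean_is_zero_without_f000():
    refl = random_reflections(4)
    m = difference_map(refl, 2, (16, 16, 16))
    assert abs(m.mean) < 1e-12


def test_grid_too_coarse_raises():
    refl = random_reflections(5, dmin=2.0)
    with pytest.raises(ValueError, match="minimum"):
        difference_map(refl, 2, (6, 6, 6))


# -------------------------------------------------------------- model SFs

def test_centred_atom_has_zero_phase_and_electron_amplitude():
    cell = UnitCell(10, 10, 10)
    s = Structure([make_atom(1, "OH", "TYR", 1, "O", (0, 0, 0), b=0.0)], cell)
    refl = structure_factors_from_model(s, dmin=3.0)
    np.testing.assert_allclose(refl.amplitudes[0], 8.0, rtol=1e-12)
    np.testing.assert_allclose(np.minimum(refl.phases_first,
                                          360 - refl.phases_first), 0.0,
                               atol=1e-8)


def test_translation_shift_theorem():
    cell = UnitCell(10, 10, 10)
    shift = np.array([0.1, 0.2, 0.3])
    s0 = Structure([make_atom(1, "OH", "TYR", 1, "O", (0, 0, 0), b=5.0)], cell)
    s1 = Structure([make_atom(1, "OH", "TYR", 1, "O", shift * 10.0, b=5.0)], cell)
    r0 = structure_factors_from_model(s0, dmin=3.0)
    r1 = structure_factors_from_model(s1, dmin=3.0)
    np.testing.assert_allclose(r1.amplitudes, r0.amplitudes, rtol=1e-10)
    expected = (r0.phases_first
                + 360.0 * r0.miller_indices @ shift) % 360.0
    diff = np.abs(expected - r1.phases_first) % 360.0
    np.testing.assert_allclose(np.minimum(diff, 360 - diff), 0.0, atol=1e-6)


def test_structure_factor_additivity():
    cell = UnitCell(12, 12, 12)
    a1 = make_atom(1, "CA", "GLY", 1, "C", (1.0, 2.0, 3.0), b=8.0)
    a2 = make_atom(2, "OH", "TYR", 2, "O", (5.0, 4.0, 6.0), b=15.0)
    r12 = structure_factors_from_model(Structure([a1, a2], cell), dmin=2.5)
    r1 = structure_factors_from_model(Structure([a1], cell), dmin=2.5)
    r2 = structure_factors_from_model(Structure([a2], cell), dmin=2.5)
    f12 = r12.amplitudes[0] * np.exp(1j * np.deg2rad(r12.phases_first))
    f1 = r1.amplitudes[0] * np.exp(1j * np.deg2rad(r1.phases_first))
    f2 = r2.amplitudes[0] * np.exp(1j * np.deg2rad(r2.phases_first))
    np.testing.assert_allclose(f12, f1 + f2, atol=1e-8)


def test_occupancy_loss_puts_map_minimum_at_the_atom():
    """The physical premise: density loss shows up as the deepest negative
    difference-map peak within a grid spacing of the damaged atom."""
    cell = UnitCell(14, 14, 14)
    atoms = [make_atom(1, "CA", "GLY", 1, "C", (3.0, 3.0, 3.0), b=12.0),
             make_atom(2, "OE1", "GLU", 2, "O", (9.0, 8.0, 7.0), b=12.0),
             make_atom(3, "CB", "ALA", 3, "C", (4.0, 10.0, 11.0), b=12.0)]
    intact = Structure(atoms, cell)
    damaged = intact.copy()
    damaged.atoms[1].occupancy = 0.6
    base = structure_factors_from_model(intact, dmin=1.8)
    later = structure_factors_from_model(damaged, dmin=1.8,
                                         hkl=base.miller_indices)
    refl = combine_datasets(base, [later.amplitudes[0]])
    shape = minimum_grid_shape(cell, 1.8)
    m = difference_map(refl, 2, shape, scale=False)
    idx = np.unravel_index(np.argmin(m.values), m.values.shape)
    frac_min = np.array(idx) / np.array(shape)
    frac_atom = cell.fractionalize(atoms[1].position)
    d = frac_min - frac_atom
    d -= np.round(d)
    dist = np.linalg.norm(cell.orthogonalize(d))
    spacing = max(cell.a / shape[0], cell.b / shape[1], cell.c / shape[2])
    assert dist <= spacing


# -------------------------------------------------------------- CCP4 maps

def test_ccp4_map_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    from dloss.reflections import DensityMap
    m = DensityMap(rng.normal(size=(8, 10, 12)), UnitCell(10, 11, 12))
    path = tmp_path / "m.ccp4"
    write_ccp4_map(m, path)
    back = read_ccp4_map(path)
    assert back.grid_shape == m.grid_shape
    assert np.abs(back.values - m.values).max() <= 1e-6 * np.abs(m.values).max()
    assert back.cell.a == pytest.approx(10.0)


def test_read_ccp4_rejects_non_map(tmp_path):
    path = tmp_path / "junk.ccp4"
    path.write_bytes(b"this is not a density map")
    with pytest.raises(ValueError):
        read_ccp4_map(path)
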