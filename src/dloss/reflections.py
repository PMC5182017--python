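"""Structure-factor amplitudes and Fobs(n)−Fobs(1) difference-map synthesis.

Difference maps use the amplitude differences between a later dataset and the
first dataset of a dose series, phased throughout with the first-dataset
phases φ_calc(1).  Negative map regions then mark electron-density loss.  Map
synthesis is done by inverse FFT on a Friedel-completed coefficient grid; a
direct Fourier summation of the same series is provided as the module's
independent oracle.

Space group is P1 throughout (synthetic series are generated in P1; real-data
adapters are expected to pre-expand symmetry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .structures import Structure, UnitCell

__all__ = [
    "ReflectionSet",
    "DensityMap",
    "read_reflections",
    "write_reflections",
    "scale_amplitudes",
    "difference_map",
    "direct_summation_map",
    "structure_factors_from_model",
    "read_ccp4_map",
    "write_ccp4_map",
    "minimum_grid_shape",
]

log = logging.getLogger(__name__)


@dataclass
class ReflectionSet:
    """Miller indices with per-dataset amplitudes and fixed first-dataset phases.

    ``amplitudes`` has shape (n_datasets, n_reflections); dataset numbering in
    the public API is 1-based (dataset 1 = reference).  One Friedel hemisphere
    is stored; F(−h) = conj(F(h)) is imposed during map synthesis.  F(000) is
    never stored.
    """

    miller_indices: np.ndarray      # (N, 3) int
    amplitudes: np.ndarray          # (n_datasets, N) float, >= 0
    phases_first: np.ndarray        # (N,) degrees in [0, 360)
    dmin: float
    cell: UnitCell

    def __post_init__(self) -> None:
        self.miller_indices = np.asarray(self.miller_indices, dtype=int)
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        self.phases_first = np.asarray(self.phases_first, dtype=float) % 360.0
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        hkl = [tuple(h) for h in self.miller_indices]
        if len(set(hkl)) != len(hkl):
            raise ValueError("duplicate (h,k,l) in reflection set")
        if (0, 0, 0) in set(hkl):
            raise ValueError("F(000) must be excluded from the reflection set")

    @property
    def n_datasets(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_reflections(self) -> int:
        return self.miller_indices.shape[0]


@dataclass
class DensityMap:
    """Real-space density on a periodic grid over the unit cell."""

    values: np.ndarray   # (nx, ny, nz)
    cell: UnitCell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3-D with every axis >= 2")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def sigma(self) -> float:
        return float(self.values.std())

    @property
    def mean(self) -> float:
        return float(self.values.mean())


# ---------------------------------------------------------------------------
# columnar reflection text I/O:  H K L F1 F2 ... PHI1, '#' comments
# ---------------------------------------------------------------------------

def read_reflections(path: str | Path, cell: UnitCell | None = None,
                     dmin: float | None = None) -> ReflectionSet:
    """Read a whitespace-separated reflection table.

    The header row names the columns ``H K L F1 F2 ... PHI1``.  A reflection
    missing any dataset amplitude is dropped (count logged).  The cell and
    dmin may be given in ``# cell: a b c alpha beta gamma`` / ``# dmin: x``
    comment lines or passed explicitly.
    """
    path = Path(path)
    header_cell, header_dmin = None, None
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#"):
            body = line[1:].strip()
            if body.lower().startswith("cell:"):
                vals = [float(x) for x in body.split(":", 1)[1].split()]
                header_cell = UnitCell(*vals)
            elif body.lower().startswith("dmin:"):
                header_dmin = float(body.split(":", 1)[1])
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    df.columns = [c.upper() for c in df.columns]
    fcols = [c for c in df.columns if c.startswith("F")]
    pcols = [c for c in df.columns if c.startswith("PHI")]
    if not {"H", "K", "L"} <= set(df.columns) or not fcols or not pcols:
        raise ValueError(f"{path}: header must name H K L, F<i> columns and PHI1")
    n_all = len(df)
    kept = df.dropna(subset=fcols + pcols)
    if len(kept) < n_all:
        log.info("%s: dropped %d reflections with missing amplitudes",
                 path, n_all - len(kept))
    hkl = kept[["H", "K", "L"]].to_numpy(dtype=int)
    amps = kept[sorted(fcols, key=lambda c: int(c[1:]))].to_numpy(dtype=float).T
    if np.any(amps < 0):
        raise ValueError(f"{path}: negative amplitude encountered")
    cell = cell or header_cell
    if cell is None:
        raise ValueError(f"{path}: no unit cell given (add a '# cell:' line)")
    if dmin is None:
        dmin = header_dmin if header_dmin is not None else float(
            cell.d_spacing(hkl).min())
    return ReflectionSet(hkl, amps, kept[pcols[0]].to_numpy(dtype=float),
                         dmin=dmin, cell=cell)


def write_reflections(refl: ReflectionSet, path: str | Path) -> None:
    path = Path(path)
    c = refl.cell
    with open(path, "w") as fh:
        fh.write(f"# cell: {c.a:.4f} {c.b:.4f} {c.c:.4f} "
                 f"{c.alpha:.3f} {c.beta:.3f} {c.gamma:.3f}\n")
        fh.write(f"# dmin: {refl.dmin:.4f}\n")
        cols = ["H", "K", "L"] + [f"F{i + 1}" for i in range(refl.n_datasets)] + ["PHI1"]
        fh.write("\t".join(cols) + "\n")
        for i in range(refl.n_reflections):
            row = [str(refl.miller_indices[i, 0]), str(refl.miller_indices[i, 1]),
                   str(refl.miller_indices[i, 2])]
            row += [f"{refl.amplitudes[d, i]:.8g}" for d in range(refl.n_datasets)]
            row.append(f"{refl.phases_first[i]:.8g}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# scaling and map synthesis
# ---------------------------------------------------------------------------

def scaling_factor(f_ref: np.ndarray, f_n: np.ndarray) -> float:
    """Least-squares scalar k minimizing Σ(k·F_n − F_ref)²."""
    denom = float(np.dot(f_n, f_n))
    if denom == 0.0:
        raise ValueError("cannot scale an all-zero amplitude set")
    return float(np.dot(f_ref, f_n) / denom)


def scale_amplitudes(refl: ReflectionSet, dataset_index: int) -> ReflectionSet:
    """Scale dataset ``dataset_index`` (1-based, >= 2) onto dataset 1."""
    if dataset_index < 2 or dataset_index > refl.n_datasets:
        raise ValueError("dataset_index must be in 2..n_datasets")
    k = scaling_factor(refl.amplitudes[0], refl.amplitudes[dataset_index - 1])
    log.info("dataset %d: overall amplitude scale k = %.6g", dataset_index, k)
    amps = refl.amplitudes.copy()
    amps[dataset_index - 1] *= k
    return replace(refl, amplitudes=amps)


def minimum_grid_shape(cell: UnitCell, dmin: float) -> tuple[int, int, int]:
    """Nyquist-adequate grid: each axis >= ceil(2·edge/dmin)."""
    return tuple(int(np.ceil(2.0 * e / dmin)) for e in (cell.a, cell.b, cell.c))


def _check_grid(refl: ReflectionSet, grid_shape: Sequence[int]) -> tuple[int, int, int]:
    need = minimum_grid_shape(refl.cell, refl.dmin)
    shape = tuple(int(n) for n in grid_shape)
    if len(shape) != 3 or any(n < m for n, m in zip(shape, need)):
        raise ValueError(
            f"grid {shape} too coarse for dmin={refl.dmin} Å; minimum {need}")
    # indices up to |h| = N/2 are representable (h = ±N/2 folds onto a real
    # exponential together with its Friedel mate, which is exact on the grid)
    hmax = np.abs(refl.miller_indices).max(axis=0)
    if any(2 * h > n for n, h in zip(shape, hmax)):
        raise ValueError(
            f"grid {shape} aliases Miller indices up to {tuple(hmax)}")
    return shape


def _delta_f(refl: ReflectionSet, dataset_index: int, scale: bool) -> np.ndarray:
    if dataset_index < 2 or dataset_index > refl.n_datasets:
        raise ValueError("dataset_index must be in 2..n_datasets")
    f1 = refl.amplitudes[0]
    fn = refl.amplitudes[dataset_index - 1]
    if scale:
        fn = fn * scaling_factor(f1, fn)
    return fn - f1


def difference_map(refl: ReflectionSet, dataset_index: int,
                   grid_shape: Sequence[int], scale: bool = True) -> DensityMap:
    """Fobs(n)−Fobs(1) map by inverse FFT with fixed φ_calc(1) phases.

    Map value at fractional x:  ρ(x) = (1/V) Σ_h ΔF·cos(φ_h − 2π h·x), the sum
    running over the Friedel-completed reflection list.  With F(000) excluded
    the map mean is zero.
    """
    shape = _check_grid(refl, grid_shape)
    dF = _delta_f(refl, dataset_index, scale)
    coeff = dF * np.exp(1j * np.deg2rad(refl.phases_first))
    grid = np.zeros(shape, dtype=complex)
    h = refl.miller_indices
    idx = tuple(np.mod(h[:, i], shape[i]) for i in range(3))
    idx_neg = tuple(np.mod(-h[:, i], shape[i]) for i in range(3))
    np.add.at(grid, idx, coeff)
    np.add.at(grid, idx_neg, np.conj(coeff))
    # Σ_h F_h exp(−2πi h·x) sampled at x = j/N is the forward DFT of the grid
    rho = np.fft.fftn(grid).real / refl.cell.volume
    return DensityMap(rho, refl.cell)


def direct_summation_map(refl: ReflectionSet, dataset_index: int,
                         grid_shape: Sequence[int], scale: bool = True) -> DensityMap:
    """The same map evaluated by explicit Fourier summation (oracle)."""
    shape = _check_grid(refl, grid_shape)
    dF = _delta_f(refl, dataset_index, scale)
    phi = np.deg2rad(refl.phases_first)
    fx = np.arange(shape[0]) / shape[0]
    fy = np.arange(shape[1]) / shape[1]
    fz = np.arange(shape[2]) / shape[2]
    rho = np.zeros(shape)
    for (h, k, l), df, ph in zip(refl.miller_indices, dF, phi):
        arg = ph - 2.0 * np.pi * (h * fx[:, None, None] + k * fy[None, :, None]
                                  + l * fz[None, None, :])
        rho += 2.0 * df * np.cos(arg)   # reflection + its Friedel mate
    return DensityMap(rho / refl.cell.volume, refl.cell)


# ---------------------------------------------------------------------------
# model structure factors (single-Gaussian atoms)
# ---------------------------------------------------------------------------

def hemisphere_indices(cell: UnitCell, dmin: float) -> np.ndarray:
    """One Friedel hemisphere of Miller indices with d >= dmin, F(000) excluded."""
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    # conservative per-axis bounds from reciprocal axis lengths
    recip_len = np.linalg.norm(cell.frac_matrix, axis=1)
    hmax = np.floor(1.0 / (dmin * recip_len)).astype(int) + 1
    rng = [np.arange(-m, m + 1) for m in hmax]
    h, k, l = np.meshgrid(*rng, indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    d = cell.d_spacing(hkl)
    keep = d >= dmin
    hkl = hkl[keep & np.isfinite(d)]
    # hemisphere: h > 0, or h == 0 and k > 0, or h == k == 0 and l > 0
    hemi = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | \
           ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0))
    hkl = hkl[hemi]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def structure_factors_from_model(structure: Structure, dmin: float,
                                 hkl: np.ndarray | None = None) -> ReflectionSet:
    """Amplitudes and phases from a single-Gaussian atom model.

    F(h) = Σ_atoms occ · n_e · exp(−B s²/4) · exp(2πi h·x_frac),  s = 1/d.
    Each atom scatters as a point of weight n_e under its isotropic B-factor
    envelope — adequate synthetic fidelity for difference-map work; not a
    Cromer–Mann scattering model.
    """
    if not structure.atoms:
        raise ValueError("empty structure")
    cell = structure.cell
    if hkl is None:
        hkl = hemisphere_indices(cell, dmin)
    hkl = np.asarray(hkl, dtype=int)
    atoms = structure.heavy_atoms()
    frac = np.mod(cell.fractionalize(structure.positions(atoms)), 1.0)
    occ = np.array([a.occupancy for a in atoms])
    ne = np.array([a.n_electrons for a in atoms], dtype=float)
    b = np.array([a.b_factor for a in atoms])
    d = cell.d_spacing(hkl)
    s2 = 1.0 / d**2
    F = np.zeros(len(hkl), dtype=complex)
    chunk = 2048
    for i0 in range(0, len(hkl), chunk):
        sl = slice(i0, i0 + chunk)
        phase = np.exp(2j * np.pi * (hkl[sl].astype(float) @ frac.T))  # (m, natoms)
        w = occ * ne * np.exp(-np.outer(s2[sl], b) / 4.0)
        F[sl] = (w * phase).sum(axis=1)
    amps = np.abs(F)
    phases = np.rad2deg(np.angle(F)) % 360.0
    return ReflectionSet(hkl, amps[None, :], phases, dmin=dmin, cell=cell)


def combine_datasets(base: ReflectionSet, later: Sequence[np.ndarray]) -> ReflectionSet:
    """Stack later-dataset amplitude vectors under dataset 1's amplitudes/phases."""
    amps = np.vstack([base.amplitudes[0]] + [np.asarray(a, dtype=float) for a in later])
    return replace(base, amplitudes=amps)


# ---------------------------------------------------------------------------
# CCP4/MRC map I/O (mode 2, via gemmi)
# ---------------------------------------------------------------------------

def write_ccp4_map(density: DensityMap, path: str | Path) -> None:
    grid = gemmi.FloatGrid(*density.grid_shape)
    grid.set_unit_cell(gemmi.UnitCell(density.cell.a, density.cell.b, density.cell.c,
                                      density.cell.alpha, density.cell.beta,
                                      density.cell.gamma))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    np.asarray(grid.array)[...] = density.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_ccp4_map(path: str | Path) -> DensityMap:
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: not a readable CCP4/MRC map ({exc})") from exc
    c = m.grid.unit_cell
    return DensityMap(np.array(m.grid.array, dtype=float),
                      UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma))
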