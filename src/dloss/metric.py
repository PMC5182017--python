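"""The per-atom, per-dose density-loss metric D_loss and its Cα normalization.

D_loss(atom, n) is the maximum density *loss* (i.e. the negated minimum of the
Fobs(n)−Fobs(1) difference map) over all grid voxels within a fixed vicinity
radius of the atom, with minimum-image distances across the periodic cell.
Values may be negative when an atom sits in a region of pure density gain; no
clamping is applied.

Cα normalization expresses each value relative to the mean D_loss of the Cα
backbone atoms at the same dose — a radiation-insensitive internal reference —
as (D_loss − <D_loss>_Cα) / <D_loss>_Cα.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reflections import (DensityMap, ReflectionSet, difference_map,
                          minimum_grid_shape)
from .structures import Atom, Structure

__all__ = [
    "DoseSeries",
    "compute_dloss",
    "vicinity_voxels",
    "ca_normalize",
    "run_series",
    "series_from_reflections",
    "DLOSS_COLUMNS",
]

log = logging.getLogger(__name__)

DLOSS_COLUMNS = ["chain", "residue_number", "residue_name", "atom_name",
                 "dataset", "dose_MGy", "dloss_raw", "dloss_sigma", "dloss_ca_norm"]

DEFAULT_VICINITY_RADIUS = 1.5  # Å; covers an atom's own density at typical resolutions


@dataclass
class DoseSeries:
    """A coordinate model with its dose ladder and per-dose difference maps.

    ``doses[0]`` is the reference dose (dataset 1); ``maps[i]`` is the
    Fobs(i+2)−Fobs(1) map.
    """

    structure: Structure
    doses: Sequence[float]
    maps: list[DensityMap]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        doses = list(self.doses)
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if len(self.maps) != len(doses) - 1:
            raise ValueError("need one difference map per dose beyond the reference")
        shapes = {m.grid_shape for m in self.maps}
        if len(shapes) > 1:
            raise ValueError("all maps must share one grid shape")
        if not self.labels:
            self.labels = [f"dataset{i + 2}" for i in range(len(self.maps))]


def vicinity_voxels(density: DensityMap, atom_position: np.ndarray,
                    radius: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid index arrays (ix, iy, iz) of voxels within ``radius`` Å of a point.

    Distances use the minimum-image convention in fractional space.  The voxel
    nearest the atom is always included, so the set is never empty.
    """
    cell = density.cell
    shape = np.array(density.grid_shape)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if 2.0 * radius > min(cell.a, cell.b, cell.c):
        raise ValueError(
            f"vicinity radius {radius} Å exceeds half the cell; reduce the radius")
    frac = np.mod(cell.fractionalize(np.asarray(atom_position, float)), 1.0)
    # per-axis fractional half-width guaranteeing coverage: |Δf_i| <= r·‖F_i‖
    half_f = radius * np.linalg.norm(cell.frac_matrix, axis=1)
    center = frac * shape
    lo = np.floor(center - half_f * shape - 1).astype(int)
    hi = np.ceil(center + half_f * shape + 1).astype(int)
    axes = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    df = idx / shape - frac
    df -= np.round(df)                       # minimum image in fractional space
    cart = df @ cell.orth_matrix.T
    dist2 = np.einsum("ij,ij->i", cart, cart)
    within = dist2 <= radius * radius
    if not np.any(within):
        within[np.argmin(dist2)] = True
    sel = np.mod(idx[within], shape)
    return sel[:, 0], sel[:, 1], sel[:, 2]


def compute_dloss(density: DensityMap, structure: Structure,
                  radius: float = DEFAULT_VICINITY_RADIUS,
                  atoms: Sequence[Atom] | None = None) -> np.ndarray:
    """D_loss for each heavy atom: max of (−map) over the vicinity sphere."""
    atoms = structure.heavy_atoms() if atoms is None else list(atoms)
    out = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        ix, iy, iz = vicinity_voxels(density, a.position, radius)
        out[i] = -density.values[ix, iy, iz].min()
    return out


def series_from_reflections(structure: Structure, refl: ReflectionSet,
                            doses: Sequence[float],
                            grid_shape: Sequence[int] | None = None,
                            labels: Sequence[str] | None = None,
                            scale: bool = True) -> DoseSeries:
    """Build a DoseSeries by synthesizing one difference map per later dataset."""
    if len(doses) != refl.n_datasets:
        raise ValueError("need one dose per dataset")
    if grid_shape is None:
        grid_shape = minimum_grid_shape(refl.cell, refl.dmin)
    maps = [difference_map(refl, n, grid_shape, scale=scale)
            for n in range(2, refl.n_datasets + 1)]
    return DoseSeries(structure, list(doses), maps,
                      list(labels) if labels else [])


def run_series(series: DoseSeries, radius: float = DEFAULT_VICINITY_RADIUS,
               dose_floor: float | None = 1.0) -> pd.DataFrame:
    """Per-atom, per-dose D_loss table with sigma-unit and Cα-normalized columns.

    Datasets at doses below ``dose_floor`` MGy (other than the reference) are
    excluded by default: specific damage other than disulfide chemistry is not
    expected below 1 MGy, so such datasets only dilute the statistics.  Pass
    ``dose_floor=None`` to disable (e.g. for a low-dose control series).
    """
    atoms = series.structure.heavy_atoms()
    rows = []
    for j, (dose, dmap, label) in enumerate(
            zip(list(series.doses)[1:], series.maps, series.labels)):
        if dose_floor is not None and dose < dose_floor:
            log.info("dataset %s at %.3g MGy below %.3g MGy floor: excluded",
                     label, dose, dose_floor)
            continue
        vals = compute_dloss(dmap, series.structure, radius, atoms)
        sigma = dmap.sigma
        for a, v in zip(atoms, vals):
            rows.append((a.chain_id, a.residue_number, a.residue_name, a.name,
                         label, dose, v, v / sigma if sigma > 0 else np.nan,
                         np.nan))
    if not rows:
        raise ValueError("no datasets remain after the dose filter")
    table = pd.DataFrame(rows, columns=DLOSS_COLUMNS)
    table.attrs["vicinity_radius"] = radius
    return ca_normalize(table)


def ca_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``dloss_ca_norm`` column: (D_loss − <D_loss>_Cα) / <D_loss>_Cα per dose."""
    table = table.copy()
    for label, grp in table.groupby("dataset"):
        ca = grp[grp["atom_name"] == "CA"]["dloss_raw"]
        if ca.empty:
            raise ValueError("structure contains no CA atoms; cannot Cα-normalize")
        mean_ca = float(ca.mean())
        if mean_ca == 0.0:
            raise ValueError(
                "mean Cα D_loss is zero at dataset %s; use raw values instead" % label)
        table.loc[grp.index, "dloss_ca_norm"] = (grp["dloss_raw"] - mean_ca) / mean_ca
    return table
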