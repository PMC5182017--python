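"""Structural covariates of Tyr –OH density loss.

Hydrogen bonds between Tyr hydroxyls and Glu/Asp carboxylate oxygens (plain
distance criterion, strict < 4 Å by default), Shrake–Rupley solvent-accessible
areas (optionally after deleting the Glu/Asp carboxylate moieties, emulating
decarboxylation), distances from Tyr –OH to disulfide bonds, and the Bdamage
metric (B-factor normalized by packing-density bin) with its relative change
between two dose states.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.StructureBuilder import StructureBuilder

from .stats import TestResult, linear_r2
from .structures import Atom, Structure

__all__ = [
    "HBondPair",
    "find_tyr_hbonds",
    "tyr_hbond_partition",
    "solvent_accessibility",
    "tyr_ring_areas",
    "disulfide_distance",
    "compute_bdamage",
    "relative_bdamage_change",
    "correlate_context",
    "DEFAULT_VDW_RADII",
]

log = logging.getLogger(__name__)

DEFAULT_VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

# atoms of the side-chain CO2 moiety removed to emulate decarboxylation
CARBOXYLATE_ATOMS: dict[str, set[str]] = {
    "GLU": {"CD", "OE1", "OE2"},
    "ASP": {"CG", "OD1", "OD2"},
}

TYR_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
ACCEPTOR_NAMES = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}


@dataclass
class HBondPair:
    donor_atom: Atom       # Tyr OH oxygen
    acceptor_atom: Atom    # Glu OE1/OE2 or Asp OD1/OD2
    distance: float


def find_tyr_hbonds(structure: Structure, cutoff: float = 4.0) -> list[HBondPair]:
    """Tyr OH – Glu/Asp carboxylate oxygen pairs at distance strictly < cutoff."""
    donors = [a for a in structure.heavy_atoms()
              if a.residue_name == "TYR" and a.name == "OH"]
    acceptors = [a for a in structure.heavy_atoms()
                 if a.name in ACCEPTOR_NAMES.get(a.residue_name, ())]
    pairs = []
    for d in donors:
        for ac in acceptors:
            dist = float(np.linalg.norm(d.position - ac.position))
            if dist < cutoff:
                pairs.append(HBondPair(d, ac, dist))
    return pairs


def tyr_hbond_partition(structure: Structure,
                        cutoff: float = 4.0) -> tuple[set, set]:
    """Partition Tyr residues into H-bonded and non-H-bonded (chain, resnum) sets."""
    all_tyr = {(a.chain_id, a.residue_number) for a in structure.heavy_atoms()
               if a.residue_name == "TYR" and a.name == "OH"}
    bonded = {(p.donor_atom.chain_id, p.donor_atom.residue_number)
              for p in find_tyr_hbonds(structure, cutoff)}
    return bonded, all_tyr - bonded


def solvent_accessibility(structure: Structure, probe: float = 1.4,
                          n_points: int = 960,
                          remove_carboxylates: bool = False,
                          radii: dict[str, float] | None = None) -> pd.Series:
    """Per-atom Shrake–Rupley solvent-accessible areas (Å²).

    With ``remove_carboxylates`` the Glu CD/OE1/OE2 and Asp CG/OD1/OD2 atoms
    are deleted before the calculation, so the returned series quantifies the
    steric environment a residue would see after decarboxylation.  Indexed by
    (chain, residue_number, atom_name).
    """
    radii = dict(DEFAULT_VDW_RADII if radii is None else radii)
    atoms = structure.heavy_atoms()
    if remove_carboxylates:
        removed = [a for a in atoms
                   if a.name in CARBOXYLATE_ATOMS.get(a.residue_name, ())]
        log.info("SASA: removed %d carboxylate atoms (Glu CD/OE1/OE2, Asp CG/OD1/OD2)",
                 len(removed))
        atoms = [a for a in atoms
                 if a.name not in CARBOXYLATE_ATOMS.get(a.residue_name, ())]
    for a in atoms:
        if a.element.upper() not in radii:
            raise ValueError(f"no van der Waals radius defined for element "
                             f"{a.element!r} (atom {a.name})")
    sb = StructureBuilder()
    sb.init_structure("s")
    sb.init_model(0)
    seen_chain = None
    seen_res = None
    for i, a in enumerate(atoms):
        if a.chain_id != seen_chain:
            sb.init_chain(a.chain_id)
            sb.init_seg(" ")
            seen_chain, seen_res = a.chain_id, None
        rid = (a.residue_number, a.residue_name)
        if rid != seen_res:
            sb.init_residue(a.residue_name, " ", a.residue_number, " ")
            seen_res = rid
        sb.init_atom(a.name, np.asarray(a.position, dtype=float), a.b_factor,
                     a.occupancy, " ", f"{a.name:^4}", i + 1,
                     element=a.element.upper())
    entity = sb.get_structure()
    ShrakeRupley(probe_radius=probe, n_points=n_points,
                 radii_dict={k.upper(): v for k, v in radii.items()}
                 ).compute(entity, level="A")
    sasa = {}
    for bio_atom, a in zip(entity.get_atoms(), atoms):
        sasa[(a.chain_id, a.residue_number, a.name)] = float(bio_atom.sasa)
    return pd.Series(sasa, name="sasa")


def tyr_ring_areas(sasa: pd.Series, structure: Structure,
                   include_oh: bool = True) -> pd.Series:
    """Per-Tyr aromatic-ring SASA: sum over CG, CD1, CD2, CE1, CE2, CZ (+ OH)."""
    names = TYR_RING_ATOMS + (("OH",) if include_oh else ())
    residues: dict[tuple[str, int], float] = {}
    for a in structure.heavy_atoms():
        if a.residue_name == "TYR" and a.name in names:
            key = (a.chain_id, a.residue_number)
            idx = (a.chain_id, a.residue_number, a.name)
            if idx in sasa.index:
                residues[key] = residues.get(key, 0.0) + float(sasa[idx])
    return pd.Series(residues, name="tyr_ring_sasa")


def disulfide_distance(structure: Structure, ss_cutoff: float = 2.5,
                       mode: str = "midpoint") -> pd.Series:
    """Distance from each Tyr OH to the nearest disulfide bond.

    Disulfides are SG–SG pairs closer than ``ss_cutoff`` Å.  ``mode`` selects
    the reference point: bond "midpoint" (default) or "nearest_s" atom.
    Returns an empty series when the structure has no disulfide.
    """
    sg = [a for a in structure.heavy_atoms()
          if a.residue_name == "CYS" and a.name == "SG"]
    bonds = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            if np.linalg.norm(sg[i].position - sg[j].position) < ss_cutoff:
                bonds.append((sg[i], sg[j]))
    if not bonds:
        return pd.Series(dtype=float, name="disulfide_distance")
    if mode == "midpoint":
        points = [0.5 * (a.position + b.position) for a, b in bonds]
    elif mode == "nearest_s":
        points = [a.position for ab in bonds for a in ab]
    else:
        raise ValueError("mode must be 'midpoint' or 'nearest_s'")
    out = {}
    for a in structure.heavy_atoms():
        if a.residue_name == "TYR" and a.name == "OH":
            out[(a.chain_id, a.residue_number)] = min(
                float(np.linalg.norm(a.position - p)) for p in points)
    return pd.Series(out, name="disulfide_distance")


def _min_image_distances2(structure: Structure, positions: np.ndarray) -> np.ndarray:
    """Pairwise squared minimum-image distances (N, N)."""
    cell = structure.cell
    frac = cell.fractionalize(positions)
    df = frac[:, None, :] - frac[None, :, :]
    df -= np.round(df)
    cart = df @ cell.orth_matrix.T
    return np.einsum("ijk,ijk->ij", cart, cart)


def compute_bdamage(structure: Structure, r_pd: float = 7.0,
                    n_bins: int = 10, min_bin_size: int = 10,
                    periodic: bool = True) -> pd.DataFrame:
    """Bdamage: atom B-factor over the mean B of its packing-density bin.

    Packing density is the count of other heavy atoms within ``r_pd`` Å,
    minimum-image by default (appropriate for a full P1 cell; with
    ``periodic=False`` distances ignore the lattice, making the metric
    invariant under arbitrary rigid motions of an isolated molecule).
    Densities are split into ``n_bins`` equal-width bins; bins with fewer
    than ``min_bin_size`` atoms are merged with their lower-density
    neighbour so every bin mean is well determined.
    """
    atoms = structure.heavy_atoms()
    pos = structure.positions(atoms)
    if periodic:
        d2 = _min_image_distances2(structure, pos)
    else:
        diff = pos[:, None, :] - pos[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, np.inf)
    pd_counts = (d2 <= r_pd * r_pd).sum(axis=1)
    b = np.array([a.b_factor for a in atoms])
    lo, hi = pd_counts.min(), pd_counts.max()
    if lo == hi:
        warnings.warn("uniform packing density: single Bdamage bin", stacklevel=2)
        edges = np.array([lo - 0.5, hi + 0.5])
    else:
        edges = np.linspace(lo, hi + 1e-9, n_bins + 1)
    bin_id = np.clip(np.digitize(pd_counts, edges) - 1, 0, len(edges) - 2)
    # merge small bins downward
    for k in sorted(set(bin_id), reverse=True):
        if (bin_id == k).sum() < min_bin_size and k > 0:
            bin_id[bin_id == k] = k - 1
    # relabel contiguously
    remap = {old: new for new, old in enumerate(sorted(set(bin_id)))}
    bin_id = np.array([remap[k] for k in bin_id])
    bdamage = np.empty(len(atoms))
    for k in set(bin_id):
        mask = bin_id == k
        bdamage[mask] = b[mask] / b[mask].mean()
    return pd.DataFrame({
        "chain": [a.chain_id for a in atoms],
        "residue_number": [a.residue_number for a in atoms],
        "residue_name": [a.residue_name for a in atoms],
        "atom_name": [a.name for a in atoms],
        "packing_density": pd_counts,
        "bin_id": bin_id,
        "bdamage": bdamage,
    })


def relative_bdamage_change(first: pd.DataFrame, second: pd.DataFrame) -> pd.Series:
    """(Bdamage_second − Bdamage_first) / Bdamage_first, matched per atom."""
    keys = ["chain", "residue_number", "atom_name"]
    a = first.set_index(keys)["bdamage"]
    b = second.set_index(keys)["bdamage"]
    common = a.index.intersection(b.index)
    return ((b[common] - a[common]) / a[common]).rename("bdamage_rel_change")


def correlate_context(dloss_table: pd.DataFrame, covariate: pd.Series,
                      min_tyr: int = 8) -> dict[str, TestResult]:
    """Linear R² of Tyr –OH D_loss against a per-residue covariate, per dataset.

    ``covariate`` is indexed by (chain, residue_number).  Series with fewer
    than ``min_tyr`` Tyr residues are skipped (logged) since an R² over a
    handful of points is not meaningful.
    """
    tyr = dloss_table[(dloss_table["residue_name"] == "TYR")
                      & (dloss_table["atom_name"] == "OH")]
    results: dict[str, TestResult] = {}
    for label, grp in tyr.groupby("dataset"):
        idx = pd.MultiIndex.from_frame(grp[["chain", "residue_number"]])
        mask = idx.isin(covariate.index)
        if mask.sum() < min_tyr:
            log.info("dataset %s: only %d Tyr with covariate values (<%d), skipped",
                     label, int(mask.sum()), min_tyr)
            continue
        x = covariate[idx[mask]].to_numpy(dtype=float)
        y = grp.loc[mask, "dloss_raw"].to_numpy(dtype=float)
        results[str(label)] = linear_r2(x, y)
    return results
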