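"""Self-contained synthetic damage series with known injected ground truth.

The generator builds a toy P1 "crystal" of idealized amino-acid side chains
(plus their Cα atoms), computes first-dataset structure factors from it, and
then emits later-dose amplitude sets from modified models in which chosen
atom types lose occupancy at a fixed rate per dose step and/or aromatic rings
are rigidly displaced.  Gaussian noise is applied to the amplitudes (the
quantity the pipeline actually ingests).  Every modification is recorded, so
recovery of the injected damage pattern by the analysis stages is a testable
statement rather than a visual impression.

The toy structure is not a protein: there is no backbone connectivity, no
lattice packing and no bulk solvent.  What it shares with real data is the
statistical structure the analysis assumes — atoms of known type in a cell,
amplitudes related to models by Fourier transform, damage as occupancy loss
or ring disorder, noise on amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .reflections import (ReflectionSet, combine_datasets,
                          structure_factors_from_model, write_ccp4_map,
                          write_reflections)
from .structures import Atom, AtomTypeKey, Structure, UnitCell, write_pdb

__all__ = [
    "DamageScenario",
    "GroundTruth",
    "make_toy_structure",
    "make_damage_series",
    "emit_fixture",
]

_BOND = {"CC": 1.52, "CO": 1.41, "CN": 1.33, "CS": 1.81, "C=O": 1.25,
         "RING": 1.39, "AR_O": 1.36, "SS": 2.05}

RING_ATOMS = {"TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
              "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")}


def _rot2(v: np.ndarray, deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], 0.0])


def _zigzag(n: int, lengths: Sequence[float]) -> list[np.ndarray]:
    """n positions along a planar zigzag chain with ~111° angles, CA at origin."""
    pts = [np.zeros(3)]
    for k in range(n - 1):
        d = _rot2(np.array([1.0, 0.0, 0.0]), 34.5 if k % 2 == 0 else -34.5)
        pts.append(pts[-1] + lengths[k] * d)
    return pts


def _chain_dir(pts: list[np.ndarray]) -> np.ndarray:
    d = pts[-1] - pts[-2]
    return d / np.linalg.norm(d)


def _residue_template(resname: str) -> list[tuple[str, str, np.ndarray]]:
    """Idealized side-chain geometry (plus CA) in a local frame, z = 0 plane."""
    L = _BOND
    if resname in ("TYR", "PHE"):
        pts = _zigzag(3, [L["CC"], L["CC"]])       # CA CB CG
        d = _chain_dir(pts)
        center = pts[2] + L["RING"] * d
        e2 = _rot2(d, 90.0)
        ring = {}
        for name, ang in [("CD1", 120.0), ("CE1", 60.0), ("CZ", 0.0),
                          ("CE2", -60.0), ("CD2", -120.0)]:
            ring[name] = center + L["RING"] * (np.cos(np.deg2rad(ang)) * d
                                               + np.sin(np.deg2rad(ang)) * e2)
        out = [("CA", "C", pts[0]), ("CB", "C", pts[1]), ("CG", "C", pts[2])]
        out += [(n, "C", p) for n, p in ring.items()]
        if resname == "TYR":
            out.append(("OH", "O", center + (L["RING"] + L["AR_O"]) * d))
        return out
    if resname == "GLU":
        pts = _zigzag(4, [L["CC"]] * 3)            # CA CB CG CD
        d = _chain_dir(pts)
        return [("CA", "C", pts[0]), ("CB", "C", pts[1]), ("CG", "C", pts[2]),
                ("CD", "C", pts[3]),
                ("OE1", "O", pts[3] + L["C=O"] * _rot2(d, 60.0)),
                ("OE2", "O", pts[3] + L["C=O"] * _rot2(d, -60.0))]
    if resname == "ASP":
        pts = _zigzag(3, [L["CC"]] * 2)
        d = _chain_dir(pts)
        return [("CA", "C", pts[0]), ("CB", "C", pts[1]), ("CG", "C", pts[2]),
                ("OD1", "O", pts[2] + L["C=O"] * _rot2(d, 60.0)),
                ("OD2", "O", pts[2] + L["C=O"] * _rot2(d, -60.0))]
    if resname == "GLN":
        pts = _zigzag(4, [L["CC"]] * 3)
        d = _chain_dir(pts)
        return [("CA", "C", pts[0]), ("CB", "C", pts[1]), ("CG", "C", pts[2]),
                ("CD", "C", pts[3]),
                ("OE1", "O", pts[3] + L["C=O"] * _rot2(d, 60.0)),
                ("NE2", "N", pts[3] + L["CN"] * _rot2(d, -60.0))]
    if resname == "ASN":
        pts = _zigzag(3, [L["CC"]] * 2)
        d = _chain_dir(pts)
        return [("CA", "C", pts[0]), ("CB", "C", pts[1]), ("CG", "C", pts[2]),
                ("OD1", "O", pts[2] + L["C=O"] * _rot2(d, 60.0)),
                ("ND2", "N", pts[2] + L["CN"] * _rot2(d, -60.0))]
    if resname == "SER":
        pts = _zigzag(3, [L["CC"], L["CO"]])
        return [("CA", "C", pts[0]), ("CB", "C", pts[1]), ("OG", "O", pts[2])]
    if resname == "THR":
        pts = _zigzag(2, [L["CC"]])
        d = _chain_dir(pts)
        return [("CA", "C", pts[0]), ("CB", "C", pts[1]),
                ("OG1", "O", pts[1] + L["CO"] * _rot2(d, 60.0)),
                ("CG2", "C", pts[1] + L["CC"] * _rot2(d, -60.0))]
    if resname == "LEU":
        pts = _zigzag(3, [L["CC"]] * 2)
        d = _chain_dir(pts)
        return [("CA", "C", pts[0]), ("CB", "C", pts[1]), ("CG", "C", pts[2]),
                ("CD1", "C", pts[2] + L["CC"] * _rot2(d, 60.0)),
                ("CD2", "C", pts[2] + L["CC"] * _rot2(d, -60.0))]
    if resname == "ILE":
        pts = _zigzag(2, [L["CC"]])
        d = _chain_dir(pts)
        cg1 = pts[1] + L["CC"] * _rot2(d, 60.0)
        d1 = (cg1 - pts[1]) / np.linalg.norm(cg1 - pts[1])
        return [("CA", "C", pts[0]), ("CB", "C", pts[1]),
                ("CG1", "C", cg1),
                ("CG2", "C", pts[1] + L["CC"] * _rot2(d, -60.0)),
                ("CD1", "C", cg1 + L["CC"] * _rot2(d1, -60.0))]
    if resname == "CYS":
        pts = _zigzag(3, [L["CC"], L["CS"]])
        return [("CA", "C", pts[0]), ("CB", "C", pts[1]), ("SG", "S", pts[2])]
    raise ValueError(f"no template for residue {resname!r}")


def _unit_single(resname: str) -> list[tuple[str, str, str, np.ndarray]]:
    return [(resname, n, e, p) for n, e, p in _residue_template(resname)]


def _unit_tyr_glu_hbond(target: float = 2.8) -> list[tuple[str, str, str, np.ndarray]]:
    """A Tyr and a Glu composed so that OH···OE1 = ``target`` Å."""
    tyr = _residue_template("TYR")
    glu = [(n, e, np.array([-p[0], -p[1], p[2]]))      # rotate 180° about z
           for n, e, p in _residue_template("GLU")]
    oh = next(p for n, _, p in tyr if n == "OH")
    oe1 = next(p for n, _, p in glu if n == "OE1")
    shift = oh + np.array([target, 0.6, 0.0]) - oe1
    shift[1] = 0.6  # slight lateral offset keeps OE2/CD clear of the ring
    out = [("TYR", n, e, p) for n, e, p in tyr]
    out += [("GLU", n, e, p + shift) for n, e, p in glu]
    return out


def _unit_disulfide() -> list[tuple[str, str, str, np.ndarray]]:
    c1 = _residue_template("CYS")
    c2 = [(n, e, np.array([-p[0], -p[1], p[2] + 0.4])) for n, e, p in _residue_template("CYS")]
    sg1 = next(p for n, _, p in c1 if n == "SG")
    sg2 = next(p for n, _, p in c2 if n == "SG")
    shift = sg1 + np.array([_BOND["SS"], 0.0, 0.3]) - sg2
    out = [("CYS", n, e, p) for n, e, p in c1]
    out += [("CYS", n, e, p + shift) for n, e, p in c2]
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_toy_structure(n_residues_per_type: int = 2, seed: int = 0,
                       site_spacing: float = 12.0,
                       min_separation: float = 2.0) -> Structure:
    """Deterministic toy P1 structure with all residue types the analysis uses.

    Contains ``max(2, n)`` free Tyr plus two Tyr hydrogen-bonded to Glu
    carboxylates (OH···OE1 = 2.8 Å), ``n`` of each other residue type, and
    ``n`` disulfide-bonded Cys pairs.  Units are placed on a cubic site grid
    and given seeded random orientations, re-drawn until no two residues
    approach closer than ``min_separation`` Å (minimum image).
    """
    n = n_residues_per_type
    if n < 1:
        raise ValueError("n_residues_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    units: list[list] = []
    units += [_unit_tyr_glu_hbond() for _ in range(2)]
    units += [_unit_disulfide() for _ in range(n)]
    for resname in ("TYR", "PHE", "GLU", "ASP", "GLN", "ASN",
                    "SER", "THR", "LEU", "ILE"):
        count = max(2, n) if resname == "TYR" else n
        units += [_unit_single(resname) for _ in range(count)]

    m = int(np.ceil(len(units) ** (1.0 / 3.0)))
    cell = UnitCell(m * site_spacing, m * site_spacing, m * site_spacing)
    sites = [(i, j, k) for i in range(m) for j in range(m) for k in range(m)]

    placed_atoms: list[Atom] = []
    placed_pos: list[np.ndarray] = []
    serial = 1
    residue_number = 0
    for unit, site in zip(units, sites):
        local = np.array([p for (_, _, _, p) in unit])
        centroid = local.mean(axis=0)
        site_center = (np.array(site) + 0.5) * site_spacing
        for attempt in range(500):
            R = _random_rotation(rng)
            coords = (local - centroid) @ R.T + site_center
            if not placed_pos:
                break
            if _min_separation_ok(np.array(placed_pos), coords, cell,
                                  min_separation):
                break
        else:
            raise ValueError("could not place residues without clashes; "
                             "increase site_spacing")
        current = None
        for (resname, aname, elem, _), xyz in zip(unit, coords):
            if aname == "CA":
                residue_number += 1
                current = residue_number
            placed_atoms.append(Atom(
                serial=serial, name=aname, altloc="", residue_name=resname,
                chain_id="A", residue_number=current, element=elem,
                position=xyz, occupancy=1.0,
                b_factor=float(rng.uniform(10.0, 20.0))))
            placed_pos.append(xyz)
            serial += 1
    return Structure(placed_atoms, cell, identifier=f"toy-seed{seed}")


def _min_separation_ok(existing: np.ndarray, new: np.ndarray,
                       cell: UnitCell, min_sep: float) -> bool:
    fe = cell.fractionalize(existing)
    fn = cell.fractionalize(new)
    df = fe[:, None, :] - fn[None, :, :]
    df -= np.round(df)
    cart = df @ cell.orth_matrix.T
    return bool((np.einsum("ijk,ijk->ij", cart, cart) >= min_sep**2).all())


# ---------------------------------------------------------------------------
# damage series generation
# ---------------------------------------------------------------------------

@dataclass
class DamageScenario:
    """Injected damage: per-dose-step occupancy-loss rates plus ring disorder.

    ``target_spec`` maps an :class:`AtomTypeKey` (or (chain, resnum, name)
    triple for an individual atom) to the fractional occupancy lost per dose
    step; dataset n carries a cumulative loss of rate·(n−1).  Amplitude noise
    is Gaussian with sd = ``noise_sigma``·mean|F|, clipped at zero.
    """

    target_spec: Mapping = field(default_factory=dict)
    ring_displacement: float = 0.0       # Å per dose step, Tyr + Phe rings
    noise_sigma: float = 0.01            # fraction of the mean amplitude
    doses: tuple[float, ...] = (0.5, 2.0, 4.0, 6.0)   # MGy, first = reference
    seed: int = 0
    dmin: float = 2.0                    # Å

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        doses = list(self.doses)
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        n_steps = len(doses) - 1
        for key, rate in self.target_spec.items():
            if not 0.0 <= rate <= 1.0 or rate * n_steps > 1.0 + 1e-12:
                raise ValueError(
                    f"cumulative occupancy loss for {key} exceeds 1")


@dataclass
class GroundTruth:
    """Record of every injected modification, per atom and dataset."""

    table: pd.DataFrame      # chain, residue_number, residue_name, atom_name,
                             # dataset, occupancy_loss, displacement
    expected_type_order: list[AtomTypeKey]

    def loss_of(self, key: AtomTypeKey, dataset: str) -> float:
        t = self.table
        sub = t[(t["residue_name"] == key.residue_name)
                & (t["atom_name"] == key.atom_name) & (t["dataset"] == dataset)]
        return float(sub["occupancy_loss"].max()) if len(sub) else 0.0


def _atom_rate(atom: Atom, spec: Mapping) -> float:
    for key, rate in spec.items():
        if isinstance(key, AtomTypeKey):
            if atom.residue_name == key.residue_name and atom.name == key.atom_name:
                return float(rate)
        elif tuple(key) == (atom.chain_id, atom.residue_number, atom.name):
            return float(rate)
    return 0.0


def make_damage_series(structure: Structure,
                       scenario: DamageScenario) -> tuple[ReflectionSet, GroundTruth]:
    """Reference + later-dose amplitude sets with φ_calc(1) and ground truth."""
    rng = np.random.default_rng(scenario.seed)
    base = structure_factors_from_model(structure, scenario.dmin)
    n_steps = len(scenario.doses) - 1
    # fixed per-residue displacement directions for ring disorder
    ring_res = sorted({(a.chain_id, a.residue_number, a.residue_name)
                       for a in structure.atoms
                       if a.residue_name in RING_ATOMS})
    directions = {}
    for key in ring_res:
        v = rng.normal(size=3)
        directions[key[:2]] = v / np.linalg.norm(v)

    later, truth_rows = [], []
    for step in range(1, n_steps + 1):
        label = f"dataset{step + 1}"
        modified = structure.copy()
        for a in modified.atoms:
            rate = _atom_rate(a, scenario.target_spec)
            loss = min(rate * step, 1.0)
            disp = 0.0
            if loss > 0:
                a.occupancy = max(0.0, a.occupancy - loss)
            if (scenario.ring_displacement > 0.0
                    and a.residue_name in RING_ATOMS
                    and a.name in RING_ATOMS[a.residue_name]):
                disp = scenario.ring_displacement * step
                a.position = a.position + disp * directions[(a.chain_id,
                                                             a.residue_number)]
            truth_rows.append((a.chain_id, a.residue_number, a.residue_name,
                               a.name, label, loss, disp))
        refl_n = structure_factors_from_model(modified, scenario.dmin,
                                              hkl=base.miller_indices)
        amps = refl_n.amplitudes[0]
        if scenario.noise_sigma > 0:
            amps = amps + rng.normal(0.0, scenario.noise_sigma * amps.mean(),
                                     size=amps.shape)
            amps = np.clip(amps, 0.0, None)
        later.append(amps)
    refl = combine_datasets(base, later)
    truth = pd.DataFrame(truth_rows, columns=[
        "chain", "residue_number", "residue_name", "atom_name",
        "dataset", "occupancy_loss", "displacement"])
    order = [k for k, _ in sorted(
        ((k, r) for k, r in scenario.target_spec.items()
         if isinstance(k, AtomTypeKey)), key=lambda kv: -kv[1])]
    return refl, GroundTruth(truth, order)


def emit_fixture(structure: Structure, refl: ReflectionSet, truth: GroundTruth,
                 scenario: DamageScenario, directory: str | Path,
                 write_maps: bool = False) -> None:
    """Write model.pdb, reflections.tsv, truth.tsv and manifest.yaml (+ maps)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_pdb(structure, directory / "model.pdb")
    write_reflections(refl, directory / "reflections.tsv")
    truth.table.to_csv(directory / "truth.tsv", sep="\t", index=False)
    manifest = {
        "identifier": structure.identifier,
        "seed": scenario.seed,
        "doses_MGy": list(scenario.doses),
        "dmin": scenario.dmin,
        "noise_sigma": scenario.noise_sigma,
        "ring_displacement": scenario.ring_displacement,
        "target_spec": {str(k): float(v) for k, v in scenario.target_spec.items()},
        "n_reflections": int(refl.n_reflections),
        "n_datasets": int(refl.n_datasets),
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    if write_maps:
        from .reflections import difference_map, minimum_grid_shape
        shape = minimum_grid_shape(refl.cell, refl.dmin)
        for n in range(2, refl.n_datasets + 1):
            write_ccp4_map(difference_map(refl, n, shape),
                           directory / f"difference_{n}.ccp4")
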