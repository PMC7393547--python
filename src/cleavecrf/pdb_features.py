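"""Parse PDB structures and compute per-residue structural descriptors.

All descriptors are computed directly from atomic coordinates:

* solvent-accessible surface area (Shrake–Rupley quadrature, probe 1.4 Å),
  split into the five Naccess-style categories (all atoms, side chain,
  main chain, non-polar side chain, polar side chain), absolute and relative;
* secondary structure by Kabsch–Sander backbone hydrogen-bond patterns,
  collapsed from eight classes to helix/strand/coil;
* backbone torsion angles (phi, psi);
* half-sphere exposure (CN, HSEAU/HSEAD from the pseudo-Cβ direction,
  HSEBU/HSEBD from the real/ideal Cβ direction);
* depth index (distance of a buried atom to the nearest solvent-accessible
  atom) and protrusion index (empty/occupied volume ratio in a 10 Å sphere);
* geometric hydrogen-bond counts, mean B-factor, and local atom packing
  density.

Residues are indexed internally by a dense 0-based index; author PDB
numbering is preserved on the `Residue` objects for I/O.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ResidueDescriptors",
    "PDBParseError",
    "ChainNotFoundError",
    "parse_pdb",
    "compute_sasa",
    "residue_accessibility",
    "assign_secondary_structure",
    "backbone_torsions",
    "half_sphere_exposure",
    "depth_index",
    "protrusion_index",
    "hydrogen_bond_counts",
    "bfactor_and_packing",
    "compute_descriptors",
    "descriptors_table",
    "chain_sequence",
    "per_residue_mean",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a usable structure."""


class ChainNotFoundError(PDBParseError):
    """Raised when the requested chain id is absent from the file."""


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# van der Waals radii (Å) keyed by element symbol; unknown elements fall
# back to the carbon radius (logged once per parse).
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75,
    "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70

# Theoretical maximum accessibility of residue X in an extended
# tripeptide context (Å²); used as the denominator for relative
# accessibility.  Residues not listed ('X') get no relative value.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

MAIN_CHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}

ACCESSIBILITY_CATEGORIES = ("all", "side", "main", "nonpolar_side", "polar_side")


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0
    serial: int = 0


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]]
    experiment: str = ""

    def residues(self) -> list[Residue]:
        """All residues, chains in insertion order."""
        out: list[Residue] = []
        for residues in self.chains.values():
            out.extend(residues)
        return out

    def atoms(self) -> list[tuple[int, Atom]]:
        """Flat (residue_index, atom) list in residue order."""
        out = []
        for ri, res in enumerate(self.residues()):
            for a in res.atoms:
                out.append((ri, a))
        return out

    def atom_coords(self) -> np.ndarray:
        ats = self.atoms()
        if not ats:
            return np.zeros((0, 3))
        return np.array([a.coord for _, a in ats], dtype=float)


@dataclass
class ResidueDescriptors:
    sasa_abs: np.ndarray        # (5,) absolute SASA per category, Å²
    sasa_rel: np.ndarray        # (5,) relative SASA per category, %
    ss8: str
    ss3: str
    phi: float                  # degrees, NaN if undefined
    psi: float
    cn: int
    hseau: int
    hsead: int
    hsebu: int
    hsebd: int
    dpx: float                  # Å, residue mean
    cx: float                   # unitless, residue mean
    hbonds: int
    bfactor_mean: float         # Å², NaN if no B-factors
    packing: float              # atoms / Å³


# ---------------------------------------------------------------------------
# parsing


def parse_pdb(path: str | Path, chain: str | None = None) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Keeps standard-residue ATOM records only (HETATM groups and waters are
    dropped), resolves alternate locations to the highest-occupancy copy
    (ties: first encountered), and discards hydrogen atoms.  When `chain`
    is given, only that chain is retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # pragma: no cover - gemmi raises rarely
        raise PDBParseError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()
    info = dict(st.info)
    experiment = info.get("_exptl.method", "")

    chains: dict[str, list[Residue]] = {}
    unknown_elements: set[str] = set()
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models in file")
    model = st[0]
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if res.name == "HOH" or res.het_flag == "H":
                continue
            # resolve altlocs: highest occupancy per atom name, ties first
            by_name: dict[str, Atom] = {}
            for a in res:
                elem = a.element.name.upper()
                if elem in ("H", "D"):
                    continue
                if elem not in VDW_RADII:
                    unknown_elements.add(elem)
                atom = Atom(
                    name=a.name,
                    element=elem,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float),
                    bfactor=float(a.b_iso),
                    occupancy=float(a.occ),
                    serial=int(a.serial),
                )
                prev = by_name.get(a.name)
                if prev is None or atom.occupancy > prev.occupancy:
                    by_name[a.name] = atom
            if not by_name:
                continue
            residues.append(
                Residue(
                    chain_id=ch.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    aa=THREE_TO_ONE.get(res.name, "X"),
                    atoms=list(by_name.values()),
                )
            )
        if residues:
            chains[ch.name] = residues

    if unknown_elements:
        logger.warning("%s: unknown elements %s assigned default vdW radius",
                       path.name, sorted(unknown_elements))
    if not chains:
        raise PDBParseError(f"{path}: no ATOM records for standard residues")
    if chain is not None:
        if chain not in chains:
            raise ChainNotFoundError(
                f"{path}: chain {chain!r} not found (available: {sorted(chains)})"
            )
        chains = {chain: chains[chain]}
    return Structure(id=path.stem, chains=chains, experiment=experiment)


def chain_sequence(structure: Structure, chain: str | None = None) -> str:
    """One-letter sequence of a chain (first chain when unspecified)."""
    if chain is None:
        chain = next(iter(structure.chains))
    if chain not in structure.chains:
        raise ChainNotFoundError(f"chain {chain!r} not in structure {structure.id}")
    return "".join(r.aa for r in structure.chains[chain])


# ---------------------------------------------------------------------------
# solvent accessibility


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def atom_radii(structure: Structure) -> np.ndarray:
    return np.array(
        [VDW_RADII.get(a.element, DEFAULT_VDW_RADIUS) for _, a in structure.atoms()],
        dtype=float,
    )


def compute_sasa(
    structure: Structure, probe: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley style.

    Each atom's solvent sphere (vdW radius + probe) is sampled at
    `n_points` quadrature points; a point is accessible when it lies
    outside every other atom's solvent sphere.
    """
    coords = structure.atom_coords()
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite atom coordinates")
    radii = atom_radii(structure) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        nb = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
              if j != i]
        if nb:
            nb_coords = coords[nb]
            nb_r = radii[nb]
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r**2)[None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * n_acc / n_points
    return areas


def residue_accessibility(
    structure: Structure, atom_sasa: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Five-category absolute (Å²) and relative (%) residue accessibility.

    Categories: all atoms, side chain, main chain, non-polar side chain
    (C/S atoms), polar side chain (N/O atoms).  Glycine's Cα counts as
    side chain, matching the reference-tool convention.  Relative values
    are percentages of the residue type's extended-state reference area;
    residue types without a reference value get NaN relative values.
    """
    residues = structure.residues()
    atoms = structure.atoms()
    if len(atom_sasa) != len(atoms):
        raise ValueError("atom_sasa length does not match structure atoms")
    abs_acc = np.zeros((len(residues), 5))
    for (ri, atom), area in zip(atoms, atom_sasa):
        res = residues[ri]
        is_main = atom.name in MAIN_CHAIN_ATOMS
        if res.aa == "G" and atom.name == "CA":
            is_main = False
        abs_acc[ri, 0] += area
        if is_main:
            abs_acc[ri, 2] += area
        else:
            abs_acc[ri, 1] += area
            if atom.element in ("N", "O"):
                abs_acc[ri, 4] += area
            else:
                abs_acc[ri, 3] += area
    rel_acc = np.full_like(abs_acc, np.nan)
    for ri, res in enumerate(residues):
        ref = MAX_ASA.get(res.aa)
        if ref is not None:
            rel_acc[ri] = 100.0 * abs_acc[ri] / ref
    return abs_acc, rel_acc


# ---------------------------------------------------------------------------
# secondary structure


_HB_Q1Q2F = 0.084 * 332.0  # electrostatic H-bond energy prefactor, kcal/mol·Å
_HB_CUTOFF = -0.5


def _backbone(residues: list[Residue]):
    """Arrays of N/CA/C/O coordinates (NaN where missing)."""
    n = len(residues)
    out = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O")}
    for i, res in enumerate(residues):
        for name in out:
            a = res.atom(name)
            if a is not None:
                out[name][i] = a.coord
    return out


def _impute_amide_h(bb: dict[str, np.ndarray]) -> np.ndarray:
    """Backbone amide H: 1.01 Å from N, bisecting N−C(prev) and N−O(prev)."""
    n = len(bb["N"])
    h = np.full((n, 3), np.nan)
    for i in range(1, n):
        N, Cp, Op = bb["N"][i], bb["C"][i - 1], bb["O"][i - 1]
        if np.isnan(N).any() or np.isnan(Cp).any() or np.isnan(Op).any():
            continue
        d1 = N - Cp
        d2 = N - Op
        n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
        if n1 < 1e-6 or n2 < 1e-6:
            continue
        direction = d1 / n1 + d2 / n2
        norm = np.linalg.norm(direction)
        if norm < 1e-6:
            continue
        h[i] = N + 1.01 * direction / norm
    return h


def _global_backbone(structure: Structure):
    """Concatenated backbone arrays, imputed amide H, and chain bookkeeping.

    Returns (bb, H, chain_of, pos_in_chain) over the dense residue index;
    H is imputed per chain (the first residue of each chain has none).
    """
    bbs, hs, chain_of, pos_in_chain = [], [], [], []
    for ci, residues in enumerate(structure.chains.values()):
        bb = _backbone(residues)
        bbs.append(bb)
        hs.append(_impute_amide_h(bb))
        chain_of.extend([ci] * len(residues))
        pos_in_chain.extend(range(len(residues)))
    bb_all = {k: np.vstack([b[k] for b in bbs]) for k in ("N", "CA", "C", "O")}
    return bb_all, np.vstack(hs), np.array(chain_of), np.array(pos_in_chain)


def _hbond_energy_matrix(structure: Structure) -> np.ndarray:
    """hb[i, j] True when the N-H of residue i donates to the C=O of j.

    Indices are dense over all chains; sequence-adjacent pairs within a
    chain are excluded, inter-chain pairs are always considered.
    """
    n = len(structure.residues())
    hb = np.zeros((n, n), dtype=bool)
    if n < 2:
        return hb
    bb, H, chain_of, pos = _global_backbone(structure)
    for i in range(n):  # donor
        if np.isnan(H[i]).any() or np.isnan(bb["N"][i]).any():
            continue
        for j in range(n):  # acceptor
            if chain_of[i] == chain_of[j] and abs(pos[i] - pos[j]) < 2:
                continue
            O, C = bb["O"][j], bb["C"][j]
            if np.isnan(O).any() or np.isnan(C).any():
                continue
            if np.linalg.norm(bb["N"][i] - O) > 5.2:
                continue
            r_on = np.linalg.norm(O - bb["N"][i])
            r_ch = np.linalg.norm(C - H[i])
            r_oh = np.linalg.norm(O - H[i])
            r_cn = np.linalg.norm(C - bb["N"][i])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e = _HB_Q1Q2F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            hb[i, j] = e < _HB_CUTOFF
    return hb


SS3_MAP = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def assign_secondary_structure(
    structure: Structure,
) -> tuple[list[str], list[str]]:
    """Kabsch–Sander-style 8-class assignment and its 3-class collapse.

    Classes H/G/I (helices) map to 'H', E/B (strands/bridges) to 'E' and
    everything else (T, S, '-') to 'L'.  Chains shorter than three
    residues, and residues with missing backbone atoms, are coil.
    """
    n = len(structure.residues())
    ss8 = ["-"] * n
    if n >= 3:
        hb = _hbond_energy_matrix(structure)
        bb, _, chain_of, pos = _global_backbone(structure)

        def same_run(i, j):
            """Residues i..j lie consecutively in one chain."""
            return chain_of[i] == chain_of[j] and pos[j] - pos[i] == j - i

        # n-turns: donor i+k accepts from i (within one chain)
        turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
        for k in (3, 4, 5):
            for i in range(n - k):
                turn[k][i] = same_run(i, i + k) and hb[i + k, i]
        helix = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
        for k in (3, 4, 5):
            for i in range(1, n - k):
                if turn[k][i - 1] and turn[k][i]:
                    helix[k][i : i + k] = True
        # bridges (within-chain separation > 2, or across chains)
        bridge = np.zeros(n, dtype=bool)

        def ok_pair(i, j):
            if not (0 <= i < n and 0 <= j < n):
                return False
            return chain_of[i] != chain_of[j] or abs(pos[i] - pos[j]) > 2

        for i in range(1, n - 1):
            for j in range(i + 1, n - 1):
                if not ok_pair(i, j):
                    continue
                if not (same_run(i - 1, i + 1) and same_run(j - 1, j + 1)):
                    continue
                para = (hb[j, i - 1] and hb[i + 1, j]) or (
                    hb[i, j - 1] and hb[j + 1, i]
                )
                anti = (hb[j, i] and hb[i, j]) or (
                    hb[j + 1, i - 1] and hb[i + 1, j - 1]
                )
                if para or anti:
                    bridge[i] = bridge[j] = True
        in_turn = np.zeros(n, dtype=bool)
        for k in (3, 4, 5):
            for i in range(n - k):
                if turn[k][i]:
                    in_turn[i + 1 : i + k] = True
        ca = bb["CA"]
        for i in range(n):
            if helix[4][i]:
                ss8[i] = "H"
            elif bridge[i]:
                neighbor = (i > 0 and bridge[i - 1] and same_run(i - 1, i)) or (
                    i < n - 1 and bridge[i + 1] and same_run(i, i + 1)
                )
                ss8[i] = "E" if neighbor else "B"
            elif helix[3][i]:
                ss8[i] = "G"
            elif helix[5][i]:
                ss8[i] = "I"
            elif in_turn[i]:
                ss8[i] = "T"
            elif i >= 2 and i < n - 2 and same_run(i - 2, i + 2):
                if not np.isnan(ca[i - 2 : i + 3]).any():
                    v1 = ca[i] - ca[i - 2]
                    v2 = ca[i + 2] - ca[i]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12
                    )
                    if math.degrees(math.acos(np.clip(cosang, -1, 1))) > 70:
                        ss8[i] = "S"
    ss3 = [SS3_MAP.get(s, "L") for s in ss8]
    return ss8, ss3


# ---------------------------------------------------------------------------
# torsions


def dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle in degrees, IUPAC sign convention, in (−180, 180].

    Returns NaN (with a warning) for degenerate/collinear geometry.
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        warnings.warn("degenerate dihedral geometry; angle undefined")
        return float("nan")
    b1u = b1 / np.linalg.norm(b1)
    m1 = np.cross(n1, b1u)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def backbone_torsions(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (phi, psi) in degrees; NaN at termini and chain breaks.

    Continuity between residues i and i+1 requires the C(i)–N(i+1)
    distance to be below 2.5 Å.
    """
    all_phi: list[float] = []
    all_psi: list[float] = []
    for residues in structure.chains.values():
        n = len(residues)
        bb = _backbone(residues)
        linked = np.zeros(n, dtype=bool)  # linked[i]: peptide bond i -> i+1
        for i in range(n - 1):
            c, nn = bb["C"][i], bb["N"][i + 1]
            if not (np.isnan(c).any() or np.isnan(nn).any()):
                linked[i] = np.linalg.norm(nn - c) < 2.5
        for i in range(n):
            phi = psi = float("nan")
            if (
                i > 0
                and linked[i - 1]
                and not np.isnan(
                    np.concatenate([bb["C"][i - 1], bb["N"][i], bb["CA"][i], bb["C"][i]])
                ).any()
            ):
                phi = dihedral(bb["C"][i - 1], bb["N"][i], bb["CA"][i], bb["C"][i])
            if (
                i < n - 1
                and linked[i]
                and not np.isnan(
                    np.concatenate([bb["N"][i], bb["CA"][i], bb["C"][i], bb["N"][i + 1]])
                ).any()
            ):
                psi = dihedral(bb["N"][i], bb["CA"][i], bb["C"][i], bb["N"][i + 1])
            all_phi.append(phi)
            all_psi.append(psi)
    return np.array(all_phi), np.array(all_psi)


# ---------------------------------------------------------------------------
# half-sphere exposure


def _pseudo_cb_direction(residues: list[Residue], i: int) -> np.ndarray | None:
    """HSE-A up direction from neighbouring Cα positions."""
    ca = residues[i].atom("CA")
    if ca is None:
        return None
    d = np.zeros(3)
    found = False
    for j in (i - 1, i + 1):
        if 0 <= j < len(residues):
            nb = residues[j].atom("CA")
            if nb is not None:
                d = d + (ca.coord - nb.coord)
                found = True
    if not found or np.linalg.norm(d) < 1e-9:
        return None
    return d / np.linalg.norm(d)


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
             length: float = 1.53) -> np.ndarray:
    """Cβ position from backbone tetrahedral geometry (L configuration)."""
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    bisector = -(u1 + u2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(u2, u1)
    perp /= np.linalg.norm(perp)
    ang = math.radians(54.75)
    return ca + length * (math.cos(ang) * bisector + math.sin(ang) * perp)


def _cb_coord(res: Residue) -> np.ndarray | None:
    cb = res.atom("CB")
    if cb is not None:
        return cb.coord
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if n is None or ca is None or c is None:
        return None
    return ideal_cb(n.coord, ca.coord, c.coord)


def half_sphere_exposure(
    structure: Structure, radius: float = 13.0
) -> dict[str, np.ndarray]:
    """Contact number and half-sphere exposure counts per residue.

    CN counts other residues' Cα atoms within `radius` of a residue's Cα;
    HSEAU/HSEAD split that count by the half-space above/below the plane
    normal to the pseudo-Cβ direction (from neighbouring Cα positions).
    HSEBU/HSEBD count neighbouring Cβ atoms (real or ideal) split along
    the Cα→Cβ direction.  When a direction is undefined, neighbours are
    assigned to the upper half-sphere.
    """
    residues = structure.residues()
    # residues grouped per chain for neighbour-based directions
    per_chain: list[list[Residue]] = list(structure.chains.values())
    chain_of: list[tuple[int, int]] = []
    for ci, res_list in enumerate(per_chain):
        for i in range(len(res_list)):
            chain_of.append((ci, i))
    n = len(residues)
    ca = np.full((n, 3), np.nan)
    cb = np.full((n, 3), np.nan)
    for i, res in enumerate(residues):
        a = res.atom("CA")
        if a is not None:
            ca[i] = a.coord
        b = _cb_coord(res)
        if b is not None:
            cb[i] = b
    out = {k: np.zeros(n, dtype=int) for k in ("cn", "hseau", "hsead", "hsebu", "hsebd")}
    for i in range(n):
        if np.isnan(ca[i]).any():
            continue
        ci, local_i = chain_of[i]
        dir_a = _pseudo_cb_direction(per_chain[ci], local_i)
        if dir_a is None and not np.isnan(cb[i]).any():
            dir_a = cb[i] - ca[i]
            dir_a = dir_a / (np.linalg.norm(dir_a) + 1e-12)
        dir_b = None
        if not np.isnan(cb[i]).any():
            dir_b = cb[i] - ca[i]
            dir_b = dir_b / (np.linalg.norm(dir_b) + 1e-12)
        for j in range(n):
            if j == i:
                continue
            if not np.isnan(ca[j]).any() and np.linalg.norm(ca[j] - ca[i]) < radius:
                out["cn"][i] += 1
                up = True if dir_a is None else np.dot(ca[j] - ca[i], dir_a) > 0
                out["hseau" if up else "hsead"][i] += 1
            if not np.isnan(cb[j]).any() and np.linalg.norm(cb[j] - ca[i]) < radius:
                up = True if dir_b is None else np.dot(cb[j] - ca[i], dir_b) > 0
                out["hsebu" if up else "hsebd"][i] += 1
    return out


# ---------------------------------------------------------------------------
# burial descriptors


def depth_index(
    structure: Structure, atom_sasa: np.ndarray, sasa_threshold: float = 0.0
) -> np.ndarray:
    """Per-atom depth index: distance to the nearest solvent-accessible atom.

    Atoms with SASA above `sasa_threshold` are surface atoms (depth 0).
    """
    coords = structure.atom_coords()
    if len(atom_sasa) != len(coords):
        raise ValueError("atom_sasa length does not match structure atoms")
    exposed = np.asarray(atom_sasa) > sasa_threshold
    if not exposed.any():
        raise ValueError("structure has no solvent-accessible atoms")
    dpx = np.zeros(len(coords))
    tree = cKDTree(coords[exposed])
    buried = ~exposed
    if buried.any():
        d, _ = tree.query(coords[buried])
        dpx[buried] = d
    return dpx


def protrusion_index(
    structure: Structure,
    sphere_radius: float = 10.0,
    mean_atom_volume: float = 20.1,
) -> np.ndarray:
    """Per-atom protrusion index cx = V_ext / V_int in a fixed sphere.

    V_int is the number of atoms within `sphere_radius` (the atom itself
    included) times `mean_atom_volume`, clamped to the sphere volume;
    V_ext is the remainder, so cx ≥ 0.
    """
    if sphere_radius <= 0:
        raise ValueError("sphere_radius must be positive")
    coords = structure.atom_coords()
    v_sphere = 4.0 / 3.0 * math.pi * sphere_radius**3
    tree = cKDTree(coords)
    counts = np.array([len(tree.query_ball_point(c, sphere_radius)) for c in coords])
    v_int = np.minimum(counts * mean_atom_volume, v_sphere)
    v_ext = v_sphere - v_int
    return v_ext / v_int


def per_residue_mean(structure: Structure, atom_values: np.ndarray) -> np.ndarray:
    """Average a per-atom quantity over each residue's atoms."""
    residues = structure.residues()
    sums = np.zeros(len(residues))
    counts = np.zeros(len(residues))
    for (ri, _), v in zip(structure.atoms(), atom_values):
        sums[ri] += v
        counts[ri] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


# ---------------------------------------------------------------------------
# hydrogen bonds


SIDE_CHAIN_DONORS = {
    "NE", "NH1", "NH2", "ND1", "NE2", "NZ", "NE1", "ND2", "OG", "OG1", "OH",
}
ACCEPTORS = {
    "O", "OXT", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH", "ND1", "NE2", "SD",
}


def hydrogen_bond_counts(
    structure: Structure, max_da: float = 3.9, min_angle: float = 90.0
) -> np.ndarray:
    """Geometric hydrogen-bond count per residue.

    A bond requires donor–acceptor distance < `max_da` Å and, where the
    donor hydrogen position is known (imputed for backbone amides), a
    D–H…A angle above `min_angle` degrees.  Each bond is credited to both
    partner residues.  Intra-residue pairs and backbone–backbone pairs of
    sequence-adjacent residues are excluded.
    """
    residues = structure.residues()
    n = len(residues)
    counts = np.zeros(n, dtype=int)
    # imputed backbone amide H per chain
    h_pos: dict[int, np.ndarray] = {}
    offset = 0
    chain_pos: dict[int, tuple[int, int]] = {}
    for ci, res_list in enumerate(structure.chains.values()):
        bb = _backbone(res_list)
        H = _impute_amide_h(bb)
        for i in range(len(res_list)):
            if not np.isnan(H[i]).any():
                h_pos[offset + i] = H[i]
            chain_pos[offset + i] = (ci, i)
        offset += len(res_list)

    donors = []  # (res_idx, atom, is_backbone)
    acceptors = []
    for ri, res in enumerate(residues):
        for a in res.atoms:
            if a.name == "N":
                donors.append((ri, a, True))
            elif a.name in SIDE_CHAIN_DONORS:
                donors.append((ri, a, False))
            if a.name in ACCEPTORS:
                acceptors.append((ri, a, a.name in ("O", "OXT")))
    for ri, datom, d_bb in donors:
        for rj, aatom, a_bb in acceptors:
            if ri == rj:
                continue
            if d_bb and a_bb:
                ci, pi = chain_pos[ri]
                cj, pj = chain_pos[rj]
                if ci == cj and abs(pi - pj) < 2:
                    continue
            dist = np.linalg.norm(datom.coord - aatom.coord)
            if dist >= max_da:
                continue
            ok = True
            if datom.name == "N" and ri in h_pos:
                h = h_pos[ri]
                v1 = datom.coord - h
                v2 = aatom.coord - h
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12
                )
                ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                ok = ang > min_angle
            if ok:
                counts[ri] += 1
                counts[rj] += 1
    return counts


# ---------------------------------------------------------------------------
# B-factor and packing


def bfactor_and_packing(
    structure: Structure, packing_radius: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean heavy-atom B-factor and local packing density per residue.

    Packing is the number of heavy atoms within `packing_radius` of the
    residue's atom centroid, divided by the sphere volume (atoms/Å³).
    """
    residues = structure.residues()
    coords = structure.atom_coords()
    tree = cKDTree(coords)
    v_sphere = 4.0 / 3.0 * math.pi * packing_radius**3
    bmean = np.full(len(residues), np.nan)
    packing = np.zeros(len(residues))
    for ri, res in enumerate(residues):
        if res.atoms:
            bmean[ri] = float(np.mean([a.bfactor for a in res.atoms]))
            centroid = res.coords().mean(axis=0)
            packing[ri] = len(tree.query_ball_point(centroid, packing_radius)) / v_sphere
    return bmean, packing


# ---------------------------------------------------------------------------
# aggregation


def compute_descriptors(structure: Structure) -> list[ResidueDescriptors]:
    """All per-residue descriptors for a structure, in residue order."""
    atom_sasa = compute_sasa(structure)
    abs_acc, rel_acc = residue_accessibility(structure, atom_sasa)
    ss8, ss3 = assign_secondary_structure(structure)
    phi, psi = backbone_torsions(structure)
    hse = half_sphere_exposure(structure)
    dpx_res = per_residue_mean(structure, depth_index(structure, atom_sasa))
    cx_res = per_residue_mean(structure, protrusion_index(structure))
    hbonds = hydrogen_bond_counts(structure)
    bmean, packing = bfactor_and_packing(structure)
    out = []
    for i in range(len(structure.residues())):
        out.append(
            ResidueDescriptors(
                sasa_abs=abs_acc[i],
                sasa_rel=rel_acc[i],
                ss8=ss8[i],
                ss3=ss3[i],
                phi=float(phi[i]),
                psi=float(psi[i]),
                cn=int(hse["cn"][i]),
                hseau=int(hse["hseau"][i]),
                hsead=int(hse["hsead"][i]),
                hsebu=int(hse["hsebu"][i]),
                hsebd=int(hse["hsebd"][i]),
                dpx=float(dpx_res[i]),
                cx=float(cx_res[i]),
                hbonds=int(hbonds[i]),
                bfactor_mean=float(bmean[i]),
                packing=float(packing[i]),
            )
        )
    return out


def descriptors_table(
    structure: Structure, descriptors: list[ResidueDescriptors] | None = None
) -> pd.DataFrame:
    """Per-residue descriptor table (one row per residue, fixed columns)."""
    if descriptors is None:
        descriptors = compute_descriptors(structure)
    rows = []
    for res, d in zip(structure.residues(), descriptors):
        row = {
            "chain": res.chain_id,
            "resnum": res.seq_number,
            "icode": res.insertion_code,
            "aa": res.aa,
            "ss8": d.ss8,
            "ss3": d.ss3,
            "phi": d.phi,
            "psi": d.psi,
            "cn": d.cn,
            "hseau": d.hseau,
            "hsead": d.hsead,
            "hsebu": d.hsebu,
            "hsebd": d.hsebd,
            "dpx": d.dpx,
            "cx": d.cx,
            "hbonds": d.hbonds,
            "bfactor_mean": d.bfactor_mean,
            "packing": d.packing,
        }
        for k, cat in enumerate(ACCESSIBILITY_CATEGORIES):
            row[f"sasa_{cat}"] = d.sasa_abs[k]
            row[f"rsa_{cat}"] = d.sasa_rel[k]
        rows.append(row)
    return pd.DataFrame(rows)
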