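"""Self-contained synthetic fixtures: toy structures and cleavage tables.

Backbones are grown residue by residue from ideal internal coordinates
(NeRF placement), so helix, strand and coil segments have exactly the
requested (phi, psi) torsions; only backbone atoms N/Cα/C/O plus an
ideal Cβ are built.  Datasets plant a cleavage signal either in the
sequence (a P4–P1 motif), in the structure (sites centred in mobile
coil segments, with elevated loop B-factors), or both; the ground truth
and the designated signal-violating negative candidates are recorded in
a JSON manifest so every downstream module can be exercised offline and
reproducibly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dataset import CleavageRecord, write_annotations
from .pdb_features import Atom, Residue, Structure, ideal_cb

__all__ = [
    "FixtureSpec",
    "build_backbone",
    "build_antiparallel_pair",
    "generate_dataset",
    "load_generated",
    "write_pdb",
    "write_fasta",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# ideal backbone geometry (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

HELIX_PHIPSI = (-57.0, -47.0)
STRAND_PHIPSI = (-119.0, 113.0)
# polyproline-II-like coil region sampled uniformly
COIL_PHI_RANGE = (-90.0, -65.0)
COIL_PSI_RANGE = (120.0, 160.0)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class FixtureSpec:
    """Study conditions for a synthetic cleavage dataset."""

    n_substrates: int = 40
    length: int = 48
    motif: str = "DEVD...."        # 8 letters over P4..P4', '.' = wildcard
    signal_mode: str = "both"      # sequence_only | structure_only | both
    loop_fraction: float = 0.35
    seed: int = 0
    protease: str = "synthetic_protease"
    # (mean, sd) of B-factors in core (helix/strand) and loop segments
    bfactor_model: tuple[tuple[float, float], tuple[float, float]] = (
        (15.0, 3.0),
        (45.0, 8.0),
    )

    def __post_init__(self):
        if self.length < 20:
            raise ValueError("substrate length must be >= 20")
        if not (0.0 <= self.loop_fraction <= 1.0):
            raise ValueError("loop_fraction must be in [0, 1]")
        if len(self.motif) > 8:
            raise ValueError("motif longer than the P4-P4' window")
        if self.signal_mode not in ("sequence_only", "structure_only", "both"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")
        self.motif = self.motif.ljust(8, ".")


# ---------------------------------------------------------------------------
# geometry


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position of atom D given A, B, C, the C–D bond length, the B–C–D
    angle, and the A–B–C–D torsion (degrees, IUPAC sign convention)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), -math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    segments: list[tuple[str, int]],
    sequence: str | None = None,
    seed: int = 0,
    chain_id: str = "A",
    structure_id: str = "SYNTH",
    bfactor_model: tuple[tuple[float, float], tuple[float, float]] = (
        (15.0, 3.0),
        (45.0, 8.0),
    ),
) -> Structure:
    """Grow an ideal backbone from (segment type, length) blocks.

    Helix segments use (phi, psi) = (−57, −47), strands (−119, 113), and
    coil draws seeded torsions from a polyproline-II-like region.  Atoms
    N/Cα/C/O and an ideal Cβ are placed; per-residue B-factors are drawn
    from the core model for helix/strand and the loop model for coil.
    """
    rng = np.random.default_rng(seed)
    torsions: list[tuple[float, float]] = []
    seg_types: list[str] = []
    for seg_type, n in segments:
        if n <= 0:
            raise ValueError("zero-length segment")
        for _ in range(n):
            if seg_type == "helix":
                torsions.append(HELIX_PHIPSI)
            elif seg_type == "strand":
                torsions.append(STRAND_PHIPSI)
            elif seg_type == "coil":
                torsions.append(
                    (rng.uniform(*COIL_PHI_RANGE), rng.uniform(*COIL_PSI_RANGE))
                )
            else:
                raise ValueError(f"unknown segment type {seg_type!r}")
            seg_types.append(seg_type)
    return _grow_chain(torsions, seg_types, sequence, rng, chain_id,
                       structure_id, bfactor_model)


def _grow_chain(
    torsions: list[tuple[float, float]],
    seg_types: list[str],
    sequence: str | None,
    rng: np.random.Generator,
    chain_id: str,
    structure_id: str,
    bfactor_model,
) -> Structure:
    n_res = len(torsions)
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length does not match total segment length")

    (core_mu, core_sd), (loop_mu, loop_sd) = bfactor_model
    coords_n = np.zeros((n_res, 3))
    coords_ca = np.zeros((n_res, 3))
    coords_c = np.zeros((n_res, 3))
    # first residue in a canonical frame
    coords_n[0] = np.zeros(3)
    coords_ca[0] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    coords_c[0] = coords_ca[0] + BOND_CA_C * np.array(
        [math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(1, n_res):
        psi_prev = torsions[i - 1][1]
        coords_n[i] = place_atom(
            coords_n[i - 1], coords_ca[i - 1], coords_c[i - 1],
            BOND_C_N, ANGLE_CA_C_N, psi_prev,
        )
        coords_ca[i] = place_atom(
            coords_ca[i - 1], coords_c[i - 1], coords_n[i],
            BOND_N_CA, ANGLE_C_N_CA, OMEGA,
        )
        coords_c[i] = place_atom(
            coords_c[i - 1], coords_n[i], coords_ca[i],
            BOND_CA_C, ANGLE_N_CA_C, torsions[i][0],
        )
    residues: list[Residue] = []
    serial = 1
    for i in range(n_res):
        psi = torsions[i][1]
        o = place_atom(
            coords_n[i], coords_ca[i], coords_c[i], BOND_C_O, ANGLE_CA_C_O,
            psi + 180.0,
        )
        cb = ideal_cb(coords_n[i], coords_ca[i], coords_c[i])
        if seg_types[i] == "coil":
            b = max(1.0, rng.normal(loop_mu, loop_sd))
        else:
            b = max(1.0, rng.normal(core_mu, core_sd))
        atoms = []
        atom_specs = [("N", "N", coords_n[i]), ("CA", "C", coords_ca[i]),
                      ("C", "C", coords_c[i]), ("O", "O", o)]
        if sequence[i] != "G":
            atom_specs.append(("CB", "C", cb))
        for name, elem, xyz in atom_specs:
            atoms.append(Atom(name=name, element=elem, coord=np.asarray(xyz),
                              bfactor=round(b, 2), occupancy=1.0, serial=serial))
            serial += 1
        residues.append(
            Residue(chain_id=chain_id, seq_number=i + 1, insertion_code="",
                    aa=sequence[i], atoms=atoms)
        )
    return Structure(id=structure_id, chains={chain_id: residues},
                     experiment="X-RAY DIFFRACTION")


# rigid placement of the second strand of the antiparallel pair fixture,
# found once by minimizing the inter-strand backbone H-bond energies of
# two mutual donor/acceptor pairs for 8-residue strands at (-139, 135)
_PAIR_ROTVEC = (-0.24112682, 0.64267065, 2.95064131)
_PAIR_TRANSLATION = (23.97567964, 12.5250903, -5.24475763)


def build_antiparallel_pair(n: int = 8) -> Structure:
    """Two ideal strands arranged as an antiparallel β pair (two chains).

    Strand torsions are the flat-sheet values (−139, 135); chain B is a
    rigid copy of chain A placed so that cross-strand backbone hydrogen
    bonds form between the central residues.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(0)
    torsions = [(-139.0, 135.0)] * n
    a = _grow_chain(torsions, ["strand"] * n, None, rng, "A", "BPAIR",
                    ((15.0, 3.0), (45.0, 8.0)))
    rot = Rotation.from_rotvec(np.array(_PAIR_ROTVEC)).as_matrix()
    t = np.array(_PAIR_TRANSLATION)
    chain_b = []
    for r in a.chains["A"]:
        atoms = [
            Atom(at.name, at.element, rot @ at.coord + t, at.bfactor,
                 at.occupancy, at.serial)
            for at in r.atoms
        ]
        chain_b.append(Residue("B", r.seq_number, "", r.aa, atoms))
    return Structure(id="BPAIR", chains={"A": a.chains["A"], "B": chain_b},
                     experiment="X-RAY DIFFRACTION")


# ---------------------------------------------------------------------------
# writers


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a minimal, deterministic PDB file (HEADER/EXPDTA/ATOM/TER/END)."""
    lines = [
        f"HEADER    SYNTHETIC SUBSTRATE                     01-JAN-00   "
        f"{structure.id[:4].upper():<4}",
        f"EXPDTA    {structure.experiment or 'X-RAY DIFFRACTION'}",
    ]
    serial = 1
    for chain_id, residues in structure.chains.items():
        for res in residues:
            res3 = ONE_TO_THREE.get(res.aa, "UNK")
            for a in res.atoms:
                x, y, z = a.coord
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name} {res3:>3s} {chain_id}"
                    f"{res.seq_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.bfactor:6.2f}"
                    f"          {a.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      "
                     f"{ONE_TO_THREE.get(residues[-1].aa, 'UNK'):>3s} "
                     f"{chain_id}{residues[-1].seq_number:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    chunks = []
    for name, seq in sequences.items():
        chunks.append(f">{name}")
        for i in range(0, len(seq), 60):
            chunks.append(seq[i : i + 60])
    Path(path).write_text("\n".join(chunks) + "\n")


# ---------------------------------------------------------------------------
# dataset generation


def _segment_layout(spec: FixtureSpec, rng: np.random.Generator):
    """Alternating structured/coil blocks covering `spec.length` residues."""
    total_coil = max(8, round(spec.loop_fraction * spec.length))
    c1 = total_coil // 2
    c2 = total_coil - c1
    structured = spec.length - total_coil
    s1 = structured // 3 + int(rng.integers(-1, 2))
    s2 = structured // 3 + int(rng.integers(-1, 2))
    s3 = structured - s1 - s2
    layout = [
        ("helix", max(3, s1)),
        ("coil", c1),
        ("strand", max(3, s2)),
        ("coil", c2),
        ("helix", max(3, s3)),
    ]
    return layout


def _segment_spans(layout) -> list[tuple[str, int, int]]:
    spans = []
    pos = 0
    for seg_type, n in layout:
        spans.append((seg_type, pos, pos + n))
        pos += n
    return spans


def _matches_motif(window: str, motif: str) -> bool:
    return all(m == "." or m == c for m, c in zip(motif, window))


def generate_dataset(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Emit PDB files, a FASTA, an annotation TSV and a JSON manifest.

    One cleavage site is planted per substrate.  Depending on the signal
    mode, positives carry the P4–P4′ motif (``sequence_only``/``both``)
    and/or sit centred in a coil segment (``structure_only``/``both``);
    the manifest lists negative candidate P1 positions that violate the
    active signal (non-coil placement for structural signal, non-motif
    windows otherwise).  All randomness derives from ``spec.seed``; two
    runs with the same spec produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records: list[CleavageRecord] = []
    sequences: dict[str, str] = {}
    manifest_substrates = []
    for s in range(spec.n_substrates):
        rng = np.random.default_rng([spec.seed, s])
        layout = _segment_layout(spec, rng)
        length = sum(n for _, n in layout)
        spans = _segment_spans(layout)
        seq = list(rng.choice(list(AA20), size=length))

        coil_spans = [sp for sp in spans if sp[0] == "coil"]
        if spec.signal_mode in ("structure_only", "both"):
            seg = coil_spans[int(rng.integers(0, len(coil_spans)))]
            p1 = (seg[1] + seg[2]) // 2
        else:
            p1 = int(rng.integers(4, length - 5))
        if spec.signal_mode in ("sequence_only", "both"):
            for k, m in enumerate(spec.motif):
                if m != ".":
                    seq[p1 - 3 + k] = m
        sequence = "".join(seq)

        # negative candidates violating the active signal (full windows only)
        neg_candidates = []
        for p in range(4, length - 5):
            if abs(p - p1) < 8:
                continue
            if spec.signal_mode in ("structure_only", "both"):
                in_structured = any(
                    t != "coil" and lo + 2 <= p < hi - 2 for t, lo, hi in spans
                )
                if not in_structured:
                    continue
            if spec.signal_mode in ("sequence_only", "both"):
                if _matches_motif(sequence[p - 3 : p + 5], spec.motif):
                    continue
            neg_candidates.append(p)

        sid = f"SYN{s:03d}"
        st = build_backbone(
            layout, sequence=sequence, seed=int(rng.integers(0, 2**31)),
            structure_id=sid, bfactor_model=spec.bfactor_model,
        )
        write_pdb(st, outdir / f"{sid}.pdb")
        sequences[sid] = sequence
        records.append(
            CleavageRecord(
                substrate_id=sid,
                protease=spec.protease,
                p1_position=p1 + 1,  # annotations are 1-based
                source_sequence=sequence,
                structure_ref=(sid, "A"),
            )
        )
        manifest_substrates.append(
            {
                "substrate_id": sid,
                "length": length,
                "segments": [[t, n] for t, n in layout],
                "positive_p1_index": p1,
                "negative_candidate_p1_indices": neg_candidates,
            }
        )
    write_fasta(sequences, outdir / "substrates.fasta")
    write_annotations(records, outdir / "annotations.tsv")
    manifest = {
        "spec": {**asdict(spec), "bfactor_model": [list(m) for m in spec.bfactor_model]},
        "files": {
            "fasta": "substrates.fasta",
            "annotations": "annotations.tsv",
            "pdb": [f"{d['substrate_id']}.pdb" for d in manifest_substrates],
        },
        "substrates": manifest_substrates,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return manifest


def load_generated(outdir: str | Path):
    """Re-read a generated fixture directory.

    Returns (records, structures, negative_positions): the parsed
    annotation records, the structures re-parsed from the emitted PDB
    files, and the per-substrate signal-violating negative candidate P1
    indices recorded in the manifest.
    """
    from .dataset import parse_annotations
    from .pdb_features import parse_pdb

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    records = parse_annotations(outdir / manifest["files"]["annotations"])
    structures = {}
    for entry in manifest["substrates"]:
        sid = entry["substrate_id"]
        structures[sid] = parse_pdb(outdir / f"{sid}.pdb", chain="A")
    negative_positions = {
        e["substrate_id"]: e["negative_candidate_p1_indices"]
        for e in manifest["substrates"]
    }
    return records, structures, negative_positions
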