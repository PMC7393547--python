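"""Cleavage annotations, site-to-structure mapping, and dataset assembly.

Annotations follow a MEROPS-style TSV schema: one row per experimentally
verified cleavage event, identifying the substrate, the protease, the
1-based P1 position (the residue N-terminal to the scissile bond) in the
substrate sequence, and optionally a (PDB id, chain) structure
reference.  Sites are mapped onto structure chains by pairwise global
alignment with a 95% identity acceptance threshold; structures solved by
methods other than X-ray crystallography are discarded; negative sites
are drawn uniformly (seeded) from non-annotated candidate positions in
equal number to the positives; redundant substrate sequences are removed
by greedy identity clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

from .encoding import (
    STRUCTURAL_FEATURES,
    CleavageDataset,
    SiteWindow,
    build_structural_profile,
    extract_windows,
)
from .pdb_features import Structure, chain_sequence, compute_descriptors

logger = logging.getLogger(__name__)

__all__ = [
    "CleavageRecord",
    "parse_annotations",
    "write_annotations",
    "map_sites_to_chain",
    "filter_xray",
    "sample_negatives",
    "redundancy_filter",
    "build_cleavage_dataset",
    "read_fasta",
    "sequence_identity",
]

REQUIRED_COLUMNS = ("substrate_id", "protease", "p1_position", "sequence")
OPTIONAL_COLUMNS = ("pdb_id", "chain")


@dataclass(frozen=True)
class CleavageRecord:
    substrate_id: str
    protease: str
    p1_position: int            # 1-based position of P1 in the substrate
    source_sequence: str
    structure_ref: tuple[str, str] | None = None  # (pdb id, chain id)

    def __post_init__(self):
        if not (1 <= self.p1_position < len(self.source_sequence)):
            raise ValueError(
                f"{self.substrate_id}: P1 position {self.p1_position} must lie "
                f"strictly inside the sequence (length {len(self.source_sequence)})"
            )

    @property
    def p1_index(self) -> int:
        """0-based index of the P1 residue."""
        return self.p1_position - 1


def parse_annotations(path: str | Path) -> list[CleavageRecord]:
    """Read a cleavage-annotation TSV into records.

    Requires columns substrate_id, protease, p1_position, sequence;
    pdb_id/chain are optional.  Malformed rows are rejected with their
    line numbers; exact duplicate rows are dropped with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        warnings.warn(f"{path}: dropped {n_before - len(df)} duplicate row(s)")
    records: list[CleavageRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header
        try:
            p1 = int(row["p1_position"])
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-integer p1_position "
                          f"{row['p1_position']!r}")
            continue
        seq = str(row["sequence"]).strip().upper()
        ref = None
        pdb_id = row.get("pdb_id")
        chain = row.get("chain")
        if isinstance(pdb_id, str) and pdb_id and isinstance(chain, str) and chain:
            ref = (pdb_id, chain)
        try:
            records.append(
                CleavageRecord(
                    substrate_id=str(row["substrate_id"]),
                    protease=str(row["protease"]),
                    p1_position=p1,
                    source_sequence=seq,
                    structure_ref=ref,
                )
            )
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: rejected rows:\n" + "\n".join(errors))
    return records


def write_annotations(records: list[CleavageRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "substrate_id": r.substrate_id,
                "protease": r.protease,
                "p1_position": r.p1_position,
                "sequence": r.source_sequence,
                "pdb_id": r.structure_ref[0] if r.structure_ref else "",
                "chain": r.structure_ref[1] if r.structure_ref else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment helpers


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="global")
    a.match_score = 2.0
    a.mismatch_score = -1.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -0.5
    return a


def _alignment_columns(aln) -> list[tuple[int | None, int | None]]:
    """Per-column (target_index, query_index) pairs; None marks a gap."""
    cols: list[tuple[int | None, int | None]] = []
    t_blocks, q_blocks = aln.aligned
    t_prev = q_prev = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for t in range(t_prev, ts):
            cols.append((t, None))
        for q in range(q_prev, qs):
            cols.append((None, q))
        for k in range(te - ts):
            cols.append((ts + k, qs + k))
        t_prev, q_prev = te, qe
    for t in range(t_prev, len(aln.target)):
        cols.append((t, None))
    for q in range(q_prev, len(aln.query)):
        cols.append((None, q))
    return cols


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment length."""
    if not seq_a or not seq_b:
        return 0.0
    aln = _aligner().align(seq_a, seq_b)[0]
    cols = _alignment_columns(aln)
    matches = sum(
        1 for t, q in cols
        if t is not None and q is not None and seq_a[t] == seq_b[q]
    )
    return matches / len(cols)


def map_sites_to_chain(
    record: CleavageRecord,
    structure: Structure,
    min_identity: float = 0.95,
) -> int | None:
    """Map an annotated P1 onto a structure chain; None when unmappable.

    The substrate sequence is globally aligned against the chain
    sequence; the mapping is accepted only when the aligned identity
    meets `min_identity` and both the P1 and P1′ columns align to
    structure residues (not gaps).  Returns the 0-based chain residue
    index of P1.
    """
    chain_id = record.structure_ref[1] if record.structure_ref else None
    chain_seq = chain_sequence(structure, chain_id)
    if not chain_seq:
        return None
    aln = _aligner().align(record.source_sequence, chain_seq)[0]
    cols = _alignment_columns(aln)
    matches = sum(
        1 for t, q in cols
        if t is not None and q is not None
        and record.source_sequence[t] == chain_seq[q]
    )
    identity = matches / len(cols)
    if identity < min_identity:
        logger.info(
            "%s: identity %.3f below threshold %.2f; site unmapped",
            record.substrate_id, identity, min_identity,
        )
        return None
    sub_to_chain = {t: q for t, q in cols if t is not None}
    p1 = sub_to_chain.get(record.p1_index)
    p1p = sub_to_chain.get(record.p1_index + 1)
    if p1 is None or p1p is None:
        logger.info("%s: P1/P1' aligned to a gap; site unmapped",
                    record.substrate_id)
        return None
    return p1


def filter_xray(structures: list[Structure]) -> list[Structure]:
    """Keep only X-ray crystallography structures.

    NMR/EM structures, and structures without a recorded experimental
    method, are excluded (the latter with a warning).
    """
    kept = []
    for st in structures:
        method = (st.experiment or "").upper()
        if "X-RAY" in method:
            kept.append(st)
        elif not method:
            warnings.warn(f"{st.id}: no experimental method recorded; excluded")
        else:
            logger.info("%s: excluded (%s)", st.id, method)
    return kept


# ---------------------------------------------------------------------------
# negative sampling


def sample_negatives(
    windows: list[SiteWindow],
    positives: set[tuple[str, int]],
    n: int | None = None,
    seed: int = 0,
) -> list[SiteWindow]:
    """Uniform, seeded, without-replacement sample of negative windows.

    `positives` holds (substrate_id, p1_index) keys of annotated sites;
    any candidate at or overlapping an annotated P1 (within the P4–P4′
    span) is excluded from the pool.  When fewer candidates than `n`
    exist, all are returned with a warning.
    """
    if n is None:
        n = len(positives)
    excluded: set[tuple[str, int]] = set()
    for sid, p1 in positives:
        for k in range(p1 - 3, p1 + 5):
            excluded.add((sid, k))
    pool = [
        w for w in windows
        if (w.substrate_id, w.p1_index) not in excluded
    ]
    rng = np.random.default_rng(seed)
    if len(pool) < n:
        warnings.warn(
            f"only {len(pool)} negative candidates available (requested {n})"
        )
        chosen = list(range(len(pool)))
    else:
        chosen = sorted(rng.choice(len(pool), size=n, replace=False))
    out = []
    for i in chosen:
        w = pool[i]
        out.append(
            SiteWindow(w.substrate_id, w.chain_id, w.p1_index, w.residues, label=0)
        )
    return out


# ---------------------------------------------------------------------------
# redundancy filtering


def redundancy_filter(
    sequences: dict[str, str] | list[str], identity_threshold: float
) -> list[str]:
    """Greedy longest-first identity clustering; returns representative ids.

    A sequence joins an existing cluster when its pairwise global
    identity to the cluster representative is at or above the threshold;
    otherwise it founds a new cluster.  With a list input the returned
    ids are stringified indices.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must be in (0, 1]")
    if isinstance(sequences, list):
        sequences = {str(i): s for i, s in enumerate(sequences)}
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    representatives: list[str] = []
    for key in order:
        seq = sequences[key]
        clustered = False
        for rep in representatives:
            if sequence_identity(sequences[rep], seq) >= identity_threshold:
                clustered = True
                break
        if not clustered:
            representatives.append(key)
    return representatives


def build_cleavage_dataset(
    records: list[CleavageRecord],
    structures: dict[str, Structure] | None = None,
    seed: int = 0,
    negative_positions: dict[str, list[int]] | None = None,
    min_identity: float = 0.95,
    features: tuple[str, ...] = STRUCTURAL_FEATURES,
) -> CleavageDataset:
    """Assemble a labelled 1:1 positive/negative window dataset.

    With structures, annotated sites are mapped onto the chains (sites
    failing the identity/gap rules are skipped with a log message) and
    each window gets its raw structural profile; sequence-only datasets
    carry no profiles.  Negatives are drawn in equal number to the
    positives, either from `negative_positions` (substrate_id → 0-based
    P1 indices, seeded subsample) or uniformly from fully covered,
    non-overlapping candidate windows.
    """
    by_substrate: dict[str, list[CleavageRecord]] = {}
    for r in records:
        by_substrate.setdefault(r.substrate_id, []).append(r)

    pos_windows: list[SiteWindow] = []
    pos_profiles: list[dict | None] = []
    all_candidates: list[SiteWindow] = []
    cand_profiles: list[dict | None] = []
    positives_keys: set[tuple[str, int]] = set()

    for sid, recs in sorted(by_substrate.items()):
        if structures is not None:
            if sid not in structures:
                logger.info("%s: no structure supplied; skipped", sid)
                continue
            st = structures[sid]
            chain_id = recs[0].structure_ref[1] if recs[0].structure_ref else (
                next(iter(st.chains))
            )
            seq = chain_sequence(st, chain_id)
            mapped = []
            for r in recs:
                p1 = map_sites_to_chain(r, st, min_identity=min_identity)
                if p1 is not None:
                    mapped.append(p1)
            if not mapped:
                continue
            descriptors = compute_descriptors(st)
            windows = extract_windows(seq, set(mapped), substrate_id=sid,
                                      chain_id=chain_id)
            profiles = [
                build_structural_profile(w, descriptors, features) for w in windows
            ]
        else:
            seq = recs[0].source_sequence
            mapped = [r.p1_index for r in recs]
            windows = extract_windows(seq, set(mapped), substrate_id=sid)
            profiles = [None] * len(windows)
        for w, p in zip(windows, profiles):
            if w.label == 1:
                pos_windows.append(w)
                pos_profiles.append(p)
                positives_keys.add((sid, w.p1_index))
            elif 3 <= w.p1_index <= len(seq) - 5:  # fully covered windows only
                all_candidates.append(w)
                cand_profiles.append(p)

    if not pos_windows:
        raise ValueError("no positive sites could be assembled")

    profile_of = {
        (w.substrate_id, w.p1_index): p
        for w, p in zip(all_candidates, cand_profiles)
    }
    if negative_positions is not None:
        pool = [
            w for w in all_candidates
            if w.p1_index in set(negative_positions.get(w.substrate_id, []))
        ]
        rng = np.random.default_rng(seed)
        n = min(len(pos_windows), len(pool))
        if n < len(pos_windows):
            warnings.warn(f"only {len(pool)} designated negatives available")
        idx = sorted(rng.choice(len(pool), size=n, replace=False))
        negatives = [
            SiteWindow(pool[i].substrate_id, pool[i].chain_id,
                       pool[i].p1_index, pool[i].residues, label=0)
            for i in idx
        ]
    else:
        negatives = sample_negatives(all_candidates, positives_keys,
                                     n=len(pos_windows), seed=seed)
    neg_profiles = [profile_of[(w.substrate_id, w.p1_index)] for w in negatives]

    return CleavageDataset(
        windows=pos_windows + negatives,
        profiles=pos_profiles + neg_profiles,
        labels=np.array([1] * len(pos_windows) + [0] * len(negatives)),
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning id → sequence (first word of header)."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                out[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip().upper())
    if name is not None:
        out[name] = "".join(chunks)
    return out
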