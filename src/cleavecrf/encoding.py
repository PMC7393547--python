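"""Candidate-site windows and CRF observation attributes.

A candidate cleavage site is the 8-residue window P4–P4′ around a
scissile bond (cleavage between P1 and P1′).  Each window position is
described by categorical attributes: the residue identity (20 amino
acids + gap), its chemical group (8 groups + gap), and one discretized
(optionally LOWESS-smoothed) bin id per enabled structural descriptor.
The Boolean feature functions of the CRF fire on these attributes, which
is why continuous descriptors must be discretized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pdb_features import ResidueDescriptors
from .smoothing import NA_BIN, SmoothingConfig, discretize, fit_bins, lowess_smooth

__all__ = [
    "AA_ALPHABET",
    "CHEMICAL_GROUPS",
    "GAP",
    "POSITIONS",
    "SiteWindow",
    "EncodedInstance",
    "FeatureSetConfig",
    "PRESETS",
    "STRUCTURAL_FEATURES",
    "DSSP_FEATURES",
    "CleavageDataset",
    "extract_windows",
    "chemical_group",
    "encode_sequence",
    "encode_chemical",
    "build_structural_profile",
    "encode_instance",
    "fit_feature_configs",
    "preset_config",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: P4–P4′ position names; cleavage is between positions 4 and 5 (P1 | P1′).
POSITIONS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")

#: the eight chemical groups partitioning the 20 amino acids
CHEMICAL_GROUPS: dict[str, str] = {
    "sulfur": "CM",
    "aliphatic1": "AGP",
    "aliphatic2": "ILV",
    "acidic": "DE",
    "basic": "HKR",
    "aromatic": "FWY",
    "amide": "NQ",
    "hydroxy": "ST",
}
_AA_TO_GROUP = {aa: g for g, aas in CHEMICAL_GROUPS.items() for aa in aas}
GROUP_NAMES = tuple(CHEMICAL_GROUPS)

#: default structural descriptor families (one 8-vector per window each)
STRUCTURAL_FEATURES = (
    "cx", "dpx",
    "sasa_all", "sasa_side", "sasa_main", "sasa_nonpolar", "sasa_polar",
    "rsa_all", "rsa_side", "rsa_main", "rsa_nonpolar", "rsa_polar",
    "packing",
    "ss_h", "ss_e", "ss_l",
    "phi", "psi", "hbonds",
    "cn", "hseau", "hsead", "hsebu", "hsebd",
    "bfactor",
)

#: the subset of descriptors derived from the secondary-structure assignment
DSSP_FEATURES = ("ss_h", "ss_e", "ss_l", "phi", "psi", "hbonds")


@dataclass
class SiteWindow:
    """One candidate cleavage site (P4–P4′ window around the scissile bond)."""

    substrate_id: str
    chain_id: str
    p1_index: int               # 0-based index of P1 in the source sequence
    residues: str               # 8 one-letter codes, '-' off-chain
    label: int = -1             # 1 positive, 0 negative, -1 unknown

    def __post_init__(self):
        if len(self.residues) != 8:
            raise ValueError("a site window has exactly 8 residue slots")


@dataclass
class EncodedInstance:
    """Length-8 chain of categorical attribute sets (the CRF observation)."""

    positions: list[list[str]]

    def __post_init__(self):
        if len(self.positions) != 8:
            raise ValueError("an encoded instance has exactly 8 positions")


@dataclass
class FeatureSetConfig:
    """Which feature families a model uses, with per-feature smoothing/bins."""

    use_sequence: bool = True
    use_chemical: bool = False
    structural: dict[str, tuple[int, int]] = field(default_factory=dict)
    # structural maps feature name -> (smoothing range, bins)


def preset_config(name: str, rng: int = 2, bins: int = 5) -> FeatureSetConfig:
    """The published feature-combination presets.

    ``seq``: sequence one-hot only; ``seq_chem`` adds chemical groups;
    ``seq_chem_real`` adds raw (unsmoothed) structural descriptors;
    ``seq_chem_smooth`` adds LOWESS-smoothed structural descriptors;
    ``seq_chem_smooth_dssp`` smooths only the secondary-structure-derived
    descriptors.
    """
    if name == "seq":
        return FeatureSetConfig(use_sequence=True, use_chemical=False)
    if name == "seq_chem":
        return FeatureSetConfig(use_sequence=True, use_chemical=True)
    if name == "seq_chem_real":
        return FeatureSetConfig(
            True, True, {f: (0, bins) for f in STRUCTURAL_FEATURES}
        )
    if name == "seq_chem_smooth":
        return FeatureSetConfig(
            True, True, {f: (rng, bins) for f in STRUCTURAL_FEATURES}
        )
    if name == "seq_chem_smooth_dssp":
        return FeatureSetConfig(
            True, True, {f: (rng, bins) for f in DSSP_FEATURES}
        )
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("seq", "seq_chem", "seq_chem_real", "seq_chem_smooth",
           "seq_chem_smooth_dssp")


# ---------------------------------------------------------------------------
# windows


def extract_windows(
    sequence: str,
    positive_p1_positions: set[int] | frozenset[int] = frozenset(),
    substrate_id: str = "",
    chain_id: str = "",
) -> list[SiteWindow]:
    """All candidate P4–P4′ windows of a sequence, labelled from positives.

    Every position with a following residue is a candidate P1 (0-based
    index of the residue N-terminal to the scissile bond); positions
    outside the chain are padded with the gap symbol.
    """
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    positives = set(positive_p1_positions)
    for p in positives:
        if not (0 <= p < len(sequence) - 1):
            raise ValueError(
                f"P1 position {p} out of range for sequence of length {len(sequence)}"
            )
    windows = []
    for p in range(len(sequence) - 1):
        chars = [
            sequence[k] if 0 <= k < len(sequence) else GAP
            for k in range(p - 3, p + 5)
        ]
        windows.append(
            SiteWindow(
                substrate_id=substrate_id,
                chain_id=chain_id,
                p1_index=p,
                residues="".join(chars),
                label=1 if p in positives else 0,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# sequence / chemical encodings


def _safe_aa(aa: str) -> str:
    if aa in AA_ALPHABET or aa == GAP:
        return aa
    if aa != "X":
        warnings.warn(f"unknown residue letter {aa!r} treated as gap")
    return GAP


def encode_sequence(w: SiteWindow) -> np.ndarray:
    """One-hot sequence encoding: 8 positions × 20 amino acids = 160 dims."""
    vec = np.zeros(8 * 20)
    for i, aa in enumerate(w.residues):
        aa = _safe_aa(aa)
        if aa != GAP:
            vec[i * 20 + AA_ALPHABET.index(aa)] = 1.0
    return vec


def chemical_group(aa: str) -> str:
    """Chemical group of an amino acid; gap/'X' map to the gap category."""
    aa = _safe_aa(aa)
    if aa == GAP:
        return "gap"
    return _AA_TO_GROUP[aa]


def encode_chemical(w: SiteWindow) -> np.ndarray:
    """One-hot chemical-group encoding: 8 positions × 8 groups = 64 dims."""
    vec = np.zeros(8 * 8)
    for i, aa in enumerate(w.residues):
        g = chemical_group(aa)
        if g != "gap":
            vec[i * 8 + GROUP_NAMES.index(g)] = 1.0
    return vec


# ---------------------------------------------------------------------------
# structural profiles


def _feature_value(d: ResidueDescriptors, name: str) -> float:
    if name == "cx":
        return d.cx
    if name == "dpx":
        return d.dpx
    if name.startswith("sasa_") or name.startswith("rsa_"):
        cats = ("all", "side", "main", "nonpolar", "polar")
        idx = cats.index(name.split("_", 1)[1])
        return float(d.sasa_abs[idx]) if name.startswith("sasa_") else float(d.sasa_rel[idx])
    if name in ("ss_h", "ss_e", "ss_l"):
        return 1.0 if d.ss3 == name[-1].upper() else 0.0
    if name == "phi":
        return d.phi
    if name == "psi":
        return d.psi
    if name == "hbonds":
        return float(d.hbonds)
    if name == "cn":
        return float(d.cn)
    if name in ("hseau", "hsead", "hsebu", "hsebd"):
        return float(getattr(d, name))
    if name == "bfactor":
        return d.bfactor_mean
    if name == "packing":
        return d.packing
    raise KeyError(f"unknown structural feature {name!r}")


def build_structural_profile(
    w: SiteWindow,
    descriptors: list[ResidueDescriptors],
    features: tuple[str, ...] = STRUCTURAL_FEATURES,
) -> dict[str, np.ndarray]:
    """Per-feature 8-value vectors for a window; NaN for off-chain positions."""
    profile: dict[str, np.ndarray] = {}
    idx = [w.p1_index - 3 + k for k in range(8)]
    for name in features:
        vec = np.full(8, np.nan)
        for k, ri in enumerate(idx):
            if 0 <= ri < len(descriptors):
                vec[k] = _feature_value(descriptors[ri], name)
        profile[name] = vec
    return profile


# ---------------------------------------------------------------------------
# instance encoding


def _smoothed(values: np.ndarray, rng: int) -> np.ndarray:
    """Smooth a window vector; missing entries bypass smoothing.

    When the vector contains NaN entries the raw finite values are kept
    (smoothing needs a complete window); NaN positions later map to the
    NA bin category.
    """
    if rng < 1 or np.isnan(values).any():
        return values
    return lowess_smooth(values, rng)


def encode_instance(
    w: SiteWindow,
    profile: dict[str, np.ndarray] | None,
    configs: dict[str, SmoothingConfig],
    use_sequence: bool = True,
    use_chemical: bool = True,
) -> EncodedInstance:
    """Categorical attributes for one window under frozen preprocessing."""
    positions: list[list[str]] = [[] for _ in range(8)]
    for i, aa in enumerate(w.residues):
        aa = _safe_aa(aa)
        if use_sequence:
            positions[i].append(f"res[{POSITIONS[i]}]={aa}")
        if use_chemical:
            positions[i].append(f"chem[{POSITIONS[i]}]={chemical_group(aa)}")
    for name, cfg in configs.items():
        if profile is None or name not in profile:
            raise KeyError(f"structural feature {name!r} not in window profile")
        values = _smoothed(profile[name], cfg.range)
        bins = discretize(values, cfg.bin_edges)
        for i, b in enumerate(bins):
            tag = "NA" if b == NA_BIN else f"b{int(b)}"
            positions[i].append(f"{name}[{POSITIONS[i]}]={tag}")
    return EncodedInstance(positions=positions)


def fit_feature_configs(
    profiles: list[dict[str, np.ndarray]],
    feature_params: dict[str, tuple[int, int]],
) -> dict[str, SmoothingConfig]:
    """Fit per-feature bin edges on training windows (smoothed first)."""
    configs: dict[str, SmoothingConfig] = {}
    for name, (rng, bins) in feature_params.items():
        pool: list[np.ndarray] = []
        for prof in profiles:
            if name not in prof:
                raise KeyError(f"structural feature {name!r} not in profiles")
            pool.append(_smoothed(prof[name], rng))
        values = np.concatenate(pool) if pool else np.zeros(0)
        values = values[np.isfinite(values)]
        if values.size == 0:
            edges = np.zeros(0)
        else:
            edges = fit_bins(values, bins)
        configs[name] = SmoothingConfig(range=rng, bins=bins, bin_edges=edges)
    return configs


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class CleavageDataset:
    """Labelled windows with (optional) raw structural profiles."""

    windows: list[SiteWindow]
    profiles: list[dict[str, np.ndarray] | None]
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.windows) == len(self.profiles) == len(self.labels)):
            raise ValueError("windows, profiles and labels must be aligned")

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, idx) -> "CleavageDataset":
        idx = np.asarray(idx)
        return CleavageDataset(
            windows=[self.windows[i] for i in idx],
            profiles=[self.profiles[i] for i in idx],
            labels=self.labels[idx],
        )

    def encode(
        self, config: FeatureSetConfig, fitted: dict[str, SmoothingConfig]
    ) -> list[EncodedInstance]:
        return [
            encode_instance(w, p, fitted, config.use_sequence, config.use_chemical)
            for w, p in zip(self.windows, self.profiles)
        ]

    def fit_preprocessing(
        self, config: FeatureSetConfig
    ) -> dict[str, SmoothingConfig]:
        if not config.structural:
            return {}
        profiles = [p for p in self.profiles if p is not None]
        if len(profiles) != len(self.profiles):
            raise ValueError("structural preset requires profiles for all windows")
        return fit_feature_configs(profiles, config.structural)
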