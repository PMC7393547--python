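"""LOWESS smoothing of 8-position feature vectors and equal-width binning.

Each structural descriptor of a candidate cleavage site is an 8-value
vector over the P4…P4′ window.  Before discretization the vector can be
smoothed by a locally weighted linear regression: for each position a
window of neighbouring positions is selected, tricube weights are
assigned, and the weighted least-squares line through the window is
evaluated at the position.  The smoothed values are then discretized
into equal-width bins whose edges are fitted on training data only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothingConfig",
    "lowess_smooth",
    "fit_bins",
    "discretize",
    "NA_BIN",
]

#: sentinel bin id for missing values
NA_BIN = -1

WINDOW_LENGTH = 8


@dataclass
class SmoothingConfig:
    """Smoothing and discretization state for one feature.

    range 0 disables smoothing (raw values are binned); bin edges are
    fitted on training data and frozen into the model.
    """

    range: int = 0
    bins: int = 1
    bin_edges: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        if not (0 <= self.range <= 5):
            raise ValueError("smoothing range must be in [0, 5]")
        if self.bins < 1:
            raise ValueError("bins must be >= 1")
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)

    def to_dict(self) -> dict:
        return {
            "range": self.range,
            "bins": self.bins,
            "bin_edges": self.bin_edges.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothingConfig":
        return cls(range=d["range"], bins=d["bins"],
                   bin_edges=np.asarray(d["bin_edges"], dtype=float))


def _window_and_weights(i: int, rng: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Window positions and tricube weights for 1-based position ``i``.

    Three cases depending on where the window would fall relative to the
    vector: a left-boundary window [1, 2·rng], a right-boundary window
    [n − 2·rng, n], or an interior window [i − rng, i + rng].  The
    tricube weight of position j is (1 − (|i − j| / h)³)³, clamped to
    [0, 1], with a case-dependent normalizer h (window half-width + 1).
    Windows are clipped to [1, n].
    """
    if i - rng < 1:
        lo, hi = 1, min(2 * rng, n)
        h = 2 * rng - i + 1
    elif i + rng > n:
        lo, hi = max(n - 2 * rng, 1), n
        h = i - (n - 2 * rng) + 1
    else:
        lo, hi = i - rng, i + rng
        h = 2 * rng + 1
    j = np.arange(lo, hi + 1)
    w = (1.0 - (np.abs(i - j) / h) ** 3) ** 3
    return j, np.clip(w, 0.0, 1.0)


def lowess_smooth(values, rng: int) -> np.ndarray:
    """Locally weighted linear smoothing of an 8-position feature vector.

    For each position i the weighted least-squares line through its
    window is evaluated at i: out[i] = m·i + (ȳ_w − m·x̄_w), where x̄_w
    and ȳ_w are the weight-normalized means over the window and m the
    weighted slope.  A degenerate window (fewer than two distinct
    positions, or zero weighted variance) falls back to the weighted
    mean.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D feature vector")
    if rng < 1:
        raise ValueError("smoothing range must be >= 1")
    if np.isnan(v).any():
        raise ValueError("missing values must be handled upstream")
    n = len(v)
    out = np.empty(n)
    for pos in range(1, n + 1):
        j, w = _window_and_weights(pos, rng, n)
        y = v[j - 1]
        norm = w.sum()
        if norm <= 0:  # pragma: no cover - weights are positive by construction
            out[pos - 1] = y.mean()
            continue
        avex = (w * j).sum() / norm
        avey = (w * y).sum() / norm
        mbot = (w * (j - avex) ** 2).sum()
        if len(j) < 2 or mbot <= 1e-300:
            logger.debug("degenerate smoothing window at position %d; "
                         "falling back to weighted mean", pos)
            out[pos - 1] = avey
            continue
        mtop = (w * (j - avex) * (y - avey)).sum()
        m = mtop / mbot
        out[pos - 1] = m * pos + (avey - m * avex)
    return out


def fit_bins(training_values, bins: int) -> np.ndarray:
    """Equal-width bin edges spanning [min, max] of the training values.

    Returns ``bins − 1`` interior edges; ``bins == 1`` (or degenerate
    training data) yields no edges, mapping everything to bin 0.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    v = np.asarray(training_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite training values to fit bins")
    lo, hi = float(v.min()), float(v.max())
    if bins == 1:
        return np.zeros(0)
    if hi <= lo:
        warnings.warn("all training values identical; collapsing to a single bin")
        return np.zeros(0)
    return lo + (hi - lo) * np.arange(1, bins) / bins


def discretize(values, bin_edges) -> np.ndarray:
    """Map values to integer bin ids given sorted edges.

    Values below the first edge map to 0, values at or above the last
    edge to the top bin (out-of-training-range values are clipped);
    boundary values go to the upper bin.  Missing values map to
    :data:`NA_BIN`.
    """
    v = np.asarray(values, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    ids = np.searchsorted(edges, v, side="right").astype(int)
    ids[~np.isfinite(v)] = NA_BIN
    return ids
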