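"""Linear-chain conditional random field with Boolean feature functions.

The model defines p(Y|X) = exp(Σ_i Σ_k λ_k f_k(y_i, y_{i−1}, x_i)) / Z(X)
over binary label chains Y (0 = non-cleavage, 1 = cleavage) given the
length-8 observation chain X of categorical attributes.  Feature
functions are indicators: a unigram feature fires when an attribute
co-occurs with a label at a position, a transition feature when a label
pair occurs on an edge (with a distinguished start state for the first
position).  Training maximizes the L2-penalized conditional
log-likelihood with a deterministic quasi-Newton optimizer from a zero
initialization; candidate sites are scored by the posterior marginal of
the cleavage label at the P1 position.

Inference (partition function, marginals, Viterbi) runs in log space via
the standard forward–backward and max-product recursions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.special import logsumexp

from .encoding import EncodedInstance

logger = logging.getLogger(__name__)

__all__ = [
    "CRFModel",
    "score",
    "log_partition",
    "marginals",
    "viterbi",
    "nll_and_gradient",
    "train",
    "predict_site",
    "save_model",
    "load_model",
]

N_LABELS = 2
CHAIN_LEN = 8
P1_POSITION = 3  # chain index of P1 within the P4..P4' window


@dataclass
class CRFModel:
    """Trained weights plus the frozen preprocessing state."""

    attr_vocab: dict[str, int]
    w_uni: np.ndarray            # (n_attrs, 2)
    w_start: np.ndarray          # (2,)
    w_trans: np.ndarray          # (2, 2) indexed [prev, next]
    l2_sigma: float = 1.0
    feature_state: dict = field(default_factory=dict)
    protease_name: str = ""
    threshold: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.w_uni = np.asarray(self.w_uni, dtype=float)
        self.w_start = np.asarray(self.w_start, dtype=float)
        self.w_trans = np.asarray(self.w_trans, dtype=float)
        if not (
            np.all(np.isfinite(self.w_uni))
            and np.all(np.isfinite(self.w_start))
            and np.all(np.isfinite(self.w_trans))
        ):
            raise ValueError("model weights must be finite")


def _as_label_seq(y) -> np.ndarray:
    """Accept a per-site label (0/1) or a full length-8 label sequence."""
    if np.isscalar(y):
        return np.full(CHAIN_LEN, int(y))
    arr = np.asarray(y, dtype=int)
    if arr.shape != (CHAIN_LEN,):
        raise ValueError(f"label sequence must have length {CHAIN_LEN}")
    return arr


def _node_scores(model: CRFModel, x: EncodedInstance) -> np.ndarray:
    """(8, 2) unigram scores; attributes outside the vocabulary contribute 0."""
    s = np.zeros((CHAIN_LEN, N_LABELS))
    for t, attrs in enumerate(x.positions):
        for a in attrs:
            idx = model.attr_vocab.get(a)
            if idx is not None:
                s[t] += model.w_uni[idx]
    return s


def score(model: CRFModel, x: EncodedInstance, y) -> float:
    """Unnormalized log-potential Σ_i Σ_k λ_k f_k(y_i, y_{i−1}, x_i)."""
    ys = _as_label_seq(y)
    s = _node_scores(model, x)
    total = model.w_start[ys[0]] + s[0, ys[0]]
    for t in range(1, CHAIN_LEN):
        total += model.w_trans[ys[t - 1], ys[t]] + s[t, ys[t]]
    return float(total)


def _forward(model: CRFModel, s: np.ndarray) -> np.ndarray:
    alpha = np.empty_like(s)
    alpha[0] = model.w_start + s[0]
    for t in range(1, CHAIN_LEN):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + model.w_trans, axis=0) + s[t]
    return alpha


def _backward(model: CRFModel, s: np.ndarray) -> np.ndarray:
    beta = np.zeros_like(s)
    for t in range(CHAIN_LEN - 2, -1, -1):
        beta[t] = logsumexp(model.w_trans + (s[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


def log_partition(model: CRFModel, x: EncodedInstance) -> float:
    """log Z(X) by the forward recursion in log space."""
    s = _node_scores(model, x)
    return float(logsumexp(_forward(model, s)[-1]))


def marginals(model: CRFModel, x: EncodedInstance) -> np.ndarray:
    """(8, 2) per-position posterior label probabilities."""
    s = _node_scores(model, x)
    alpha = _forward(model, s)
    beta = _backward(model, s)
    logz = logsumexp(alpha[-1])
    return np.exp(alpha + beta - logz)


def viterbi(model: CRFModel, x: EncodedInstance) -> tuple[list[int], float]:
    """Most probable label sequence and its probability.

    Ties break toward label 0 (argmax keeps the first maximizer).
    """
    s = _node_scores(model, x)
    delta = np.empty_like(s)
    back = np.zeros((CHAIN_LEN, N_LABELS), dtype=int)
    delta[0] = model.w_start + s[0]
    for t in range(1, CHAIN_LEN):
        cand = delta[t - 1][:, None] + model.w_trans  # [prev, next]
        back[t] = np.argmax(cand, axis=0)
        delta[t] = cand[back[t], np.arange(N_LABELS)] + s[t]
    path = [int(np.argmax(delta[-1]))]
    for t in range(CHAIN_LEN - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    logz = logsumexp(_forward(model, s)[-1])
    return path, float(np.exp(delta[-1].max() - logz))


def predict_site(model: CRFModel, x: EncodedInstance) -> float:
    """Cleavage probability: posterior of label 1 at the P1 chain position."""
    return float(marginals(model, x)[P1_POSITION, 1])


# ---------------------------------------------------------------------------
# training (vectorized across instances)


class _Packed:
    """Sparse attribute design matrix for a batch of length-8 chains."""

    def __init__(self, instances: list[EncodedInstance], attr_vocab: dict[str, int]):
        rows, cols = [], []
        for n, inst in enumerate(instances):
            for t, attrs in enumerate(inst.positions):
                r = n * CHAIN_LEN + t
                for a in attrs:
                    idx = attr_vocab.get(a)
                    if idx is not None:
                        rows.append(r)
                        cols.append(idx)
        self.n = len(instances)
        self.M = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(self.n * CHAIN_LEN, len(attr_vocab)),
        )


def _unpack(theta: np.ndarray, n_attrs: int):
    a = n_attrs * N_LABELS
    w_uni = theta[:a].reshape(n_attrs, N_LABELS)
    w_start = theta[a : a + N_LABELS]
    w_trans = theta[a + N_LABELS :].reshape(N_LABELS, N_LABELS)
    return w_uni, w_start, w_trans


def _batch_nll_grad(
    theta: np.ndarray,
    packed: _Packed,
    y_onehot: np.ndarray,      # (n*8, 2)
    emp_start: np.ndarray,     # (2,)
    emp_trans: np.ndarray,     # (2, 2)
    l2_sigma: float,
) -> tuple[float, np.ndarray]:
    n = packed.n
    n_attrs = packed.M.shape[1]
    w_uni, w_start, w_trans = _unpack(theta, n_attrs)

    s = (packed.M @ w_uni).reshape(n, CHAIN_LEN, N_LABELS)
    # forward
    alpha = np.empty_like(s)
    alpha[:, 0] = w_start[None, :] + s[:, 0]
    for t in range(1, CHAIN_LEN):
        alpha[:, t] = (
            logsumexp(alpha[:, t - 1, :, None] + w_trans[None, :, :], axis=1)
            + s[:, t]
        )
    logz = logsumexp(alpha[:, -1], axis=1)
    # backward
    beta = np.zeros_like(s)
    for t in range(CHAIN_LEN - 2, -1, -1):
        beta[:, t] = logsumexp(
            w_trans[None, :, :] + (s[:, t + 1] + beta[:, t + 1])[:, None, :], axis=2
        )
    node_marg = np.exp(alpha + beta - logz[:, None, None])
    pair_marg = np.exp(
        alpha[:, :-1, :, None]
        + w_trans[None, None, :, :]
        + (s[:, 1:] + beta[:, 1:])[:, :, None, :]
        - logz[:, None, None, None]
    )

    # empirical (observed) path score
    flat_s = s.reshape(n * CHAIN_LEN, N_LABELS)
    obs_score = (flat_s * y_onehot).sum() + emp_start @ w_start + (
        emp_trans * w_trans
    ).sum()
    nll = logz.sum() - obs_score + (theta @ theta) / (2.0 * l2_sigma**2)

    g_uni = packed.M.T @ (node_marg.reshape(n * CHAIN_LEN, N_LABELS) - y_onehot)
    g_start = node_marg[:, 0].sum(axis=0) - emp_start
    g_trans = pair_marg.sum(axis=(0, 1)) - emp_trans
    grad = np.concatenate([np.asarray(g_uni).ravel(), g_start, g_trans.ravel()])
    grad += theta / l2_sigma**2
    return float(nll), grad


def _empirical_stats(labels: list[np.ndarray]):
    n = len(labels)
    y_onehot = np.zeros((n * CHAIN_LEN, N_LABELS))
    emp_start = np.zeros(N_LABELS)
    emp_trans = np.zeros((N_LABELS, N_LABELS))
    for i, ys in enumerate(labels):
        for t, y in enumerate(ys):
            y_onehot[i * CHAIN_LEN + t, y] = 1.0
        emp_start[ys[0]] += 1.0
        for t in range(1, CHAIN_LEN):
            emp_trans[ys[t - 1], ys[t]] += 1.0
    return y_onehot, emp_start, emp_trans


def build_vocab(instances: list[EncodedInstance]) -> dict[str, int]:
    """Deterministic attribute vocabulary (sorted) from training instances."""
    attrs = sorted({a for inst in instances for pos in inst.positions for a in pos})
    return {a: i for i, a in enumerate(attrs)}


def nll_and_gradient(
    model: CRFModel, instances: list[EncodedInstance], labels
) -> tuple[float, np.ndarray]:
    """Penalized negative log-likelihood and its gradient at the model's weights.

    The gradient is ordered (unigram weights row-major, start weights,
    transition weights row-major); the penalty is ‖λ‖²/(2σ²).
    """
    if not instances:
        raise ValueError("empty instance list")
    label_seqs = [_as_label_seq(y) for y in labels]
    packed = _Packed(instances, model.attr_vocab)
    y1, es, et = _empirical_stats(label_seqs)
    theta = np.concatenate(
        [model.w_uni.ravel(), model.w_start, model.w_trans.ravel()]
    )
    return _batch_nll_grad(theta, packed, y1, es, et, model.l2_sigma)


def train(
    instances: list[EncodedInstance],
    labels,
    l2_sigma: float = 1.0,
    max_iter: int = 300,
    grad_tol: float = 1e-5,
    feature_state: dict | None = None,
    protease_name: str = "",
) -> CRFModel:
    """Fit CRF weights by penalized maximum likelihood (L-BFGS from zero).

    `labels` holds one site label (0/1) or one length-8 label sequence
    per instance.  Training is deterministic: the vocabulary is sorted
    and the optimizer starts from λ = 0 (the objective is convex).
    """
    if not instances:
        raise ValueError("empty instance list")
    label_seqs = [_as_label_seq(y) for y in labels]
    site_labels = {int(ys[P1_POSITION]) for ys in label_seqs}
    if site_labels != {0, 1}:
        raise ValueError("training requires at least one positive and one "
                         "negative instance")
    vocab = build_vocab(instances)
    if not vocab:
        raise ValueError("degenerate vocabulary: instances carry no attributes")
    packed = _Packed(instances, vocab)
    y1, es, et = _empirical_stats(label_seqs)
    n_params = len(vocab) * N_LABELS + N_LABELS + N_LABELS * N_LABELS
    theta0 = np.zeros(n_params)
    result = scipy.optimize.minimize(
        _batch_nll_grad,
        theta0,
        args=(packed, y1, es, et, l2_sigma),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": grad_tol, "ftol": 1e-12},
    )
    if not result.success and "ITERATIONS" not in str(result.message).upper():
        logger.warning("CRF optimizer stopped early: %s", result.message)
    w_uni, w_start, w_trans = _unpack(result.x, len(vocab))
    return CRFModel(
        attr_vocab=vocab,
        w_uni=w_uni,
        w_start=w_start,
        w_trans=w_trans,
        l2_sigma=l2_sigma,
        feature_state=feature_state or {},
        protease_name=protease_name,
        metadata={
            "n_instances": len(instances),
            "final_nll": float(result.fun),
            "n_iterations": int(result.nit),
            "converged": bool(result.success),
        },
    )


def predict_sites(model: CRFModel, instances: list[EncodedInstance]) -> np.ndarray:
    """Vectorized P1-marginal cleavage probabilities for a batch."""
    if not instances:
        return np.zeros(0)
    packed = _Packed(instances, model.attr_vocab)
    s = (packed.M @ model.w_uni).reshape(packed.n, CHAIN_LEN, N_LABELS)
    alpha = np.empty_like(s)
    alpha[:, 0] = model.w_start[None, :] + s[:, 0]
    for t in range(1, CHAIN_LEN):
        alpha[:, t] = (
            logsumexp(alpha[:, t - 1, :, None] + model.w_trans[None, :, :], axis=1)
            + s[:, t]
        )
    logz = logsumexp(alpha[:, -1], axis=1)
    beta = np.zeros_like(s)
    for t in range(CHAIN_LEN - 2, -1, -1):
        beta[:, t] = logsumexp(
            model.w_trans[None, :, :] + (s[:, t + 1] + beta[:, t + 1])[:, None, :],
            axis=2,
        )
    marg = np.exp(alpha[:, P1_POSITION] + beta[:, P1_POSITION] - logz[:, None])
    return marg[:, 1]


# ---------------------------------------------------------------------------
# serialization


def save_model(model: CRFModel, path: str | Path) -> None:
    """Write a self-describing JSON model file (byte-stable for equal content)."""
    doc = {
        "format": "cleavecrf-model",
        "version": 1,
        "protease_name": model.protease_name,
        "l2_sigma": model.l2_sigma,
        "threshold": model.threshold,
        "attr_vocab": model.attr_vocab,
        "w_uni": model.w_uni.tolist(),
        "w_start": model.w_start.tolist(),
        "w_trans": model.w_trans.tolist(),
        "feature_state": model.feature_state,
        "metadata": model.metadata,
    }
    Path(path).write_text(
        json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n"
    )


def load_model(path: str | Path) -> CRFModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "cleavecrf-model":
        raise ValueError(f"{path}: not a cleavecrf model file")
    return CRFModel(
        attr_vocab=doc["attr_vocab"],
        w_uni=np.asarray(doc["w_uni"]),
        w_start=np.asarray(doc["w_start"]),
        w_trans=np.asarray(doc["w_trans"]),
        l2_sigma=doc["l2_sigma"],
        feature_state=doc["feature_state"],
        protease_name=doc["protease_name"],
        threshold=doc["threshold"],
        metadata=doc["metadata"],
    )
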