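"""Training objectives: linear-kernel MMD, center-alignment losses with
gradient penalty, label-smoothing cross-entropy, MMD-based fusion weights,
the warm-up schedule and the total loss.

Every function here is a pure value-level computation on feature batches;
the analytic gradients used by the optimizer live in :mod:`misnet.training`
and are cross-checked against these values by finite differences in the
test suite.

Loss semantics
--------------
``mmd_linear``
    Linear-kernel maximum mean discrepancy between two equal-size
    batches.  With the linear kernel the RKHS mean embedding is the
    batch mean, so the statistic collapses to the squared Euclidean norm
    of the difference of batch means — equivalently the mean over all
    entries of ``D @ D.T`` with ``D`` the row-wise difference matrix.
``center_distance``
    Distance between the *centers* (batch-mean vectors) of two feature
    clouds; L1 by default.  The center-alignment losses act on domain
    centers rather than full distributions to keep the objective cheap.
``gradient_penalty``
    Two-sided soft Lipschitz-1 constraint in the style of WGAN-GP:
    penalize ``(||grad|| - 1)^2`` of the summed encoder output at random
    interpolates between two batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "LossBundle",
    "mmd_linear",
    "center_distance",
    "was_loss",
    "gradient_penalty",
    "was_gp",
    "diff_gp",
    "label_smoothing_ce",
    "smoothed_targets",
    "softmax",
    "fusion_weights",
    "alpha_schedule",
    "schedule_values",
    "total_loss",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mmd_linear(FS: np.ndarray, FT: np.ndarray) -> float:
    """Linear-kernel MMD between matched batches ``FS`` and ``FT``.

    Requires equal batch sizes (the training sampler pairs rows); equals
    ``||mean(FS) - mean(FT)||^2`` exactly, hence satisfies the
    constant-shift identity ``mmd_linear(F, F + c) == ||c||^2``.
    """
    FS = np.asarray(FS, dtype=float)
    FT = np.asarray(FT, dtype=float)
    if FS.shape != FT.shape:
        raise ValueError(
            f"mmd_linear requires matched batches, got {FS.shape} vs {FT.shape}"
        )
    if FS.shape[0] == 0:
        raise ValueError("mmd_linear: empty batch")
    d = FS.mean(axis=0) - FT.mean(axis=0)
    return float(d @ d)


def center_distance(Fa: np.ndarray, Fb: np.ndarray, norm: str = "l1") -> float:
    """Distance between batch-mean vectors (batch sizes may differ)."""
    Fa = np.asarray(Fa, dtype=float)
    Fb = np.asarray(Fb, dtype=float)
    if Fa.size == 0 or Fb.size == 0:
        raise ValueError("center_distance: empty batch")
    if Fa.shape[1] != Fb.shape[1]:
        raise ValueError(
            f"center_distance: width mismatch {Fa.shape[1]} vs {Fb.shape[1]}"
        )
    d = Fa.mean(axis=0) - Fb.mean(axis=0)
    if norm == "l1":
        return float(np.abs(d).sum())
    if norm == "l2":
        return float(np.sqrt(d @ d))
    raise ValueError(f"unknown center norm {norm!r}")


def was_loss(i: int, target_private: Sequence[np.ndarray],
             norm: str = "l1") -> float:
    """Sum of center distances from private branch ``i`` to all others.

    ``target_private`` holds the target-batch outputs of every private
    encoder; only branch ``i`` receives gradients during training (the
    other branches' contributions are treated as constants), which is
    what keeps an outlier source domain from steering the others.
    """
    n = len(target_private)
    if not (0 <= i < n):
        raise IndexError(f"branch index {i} out of range for {n} branches")
    if n == 1:
        warnings.warn("was_loss with a single source domain is identically 0",
                      stacklevel=2)
        return 0.0
    return float(sum(center_distance(target_private[i], target_private[j], norm)
                     for j in range(n) if j != i))


def _interpolates(A: np.ndarray, B: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"endpoint batches must match, got {A.shape} vs {B.shape}")
    u = rng.uniform(size=(A.shape[0], 1))
    return u * A + (1.0 - u) * B


def gradient_penalty(map_fn: Callable[[np.ndarray], np.ndarray],
                     A: np.ndarray, B: np.ndarray,
                     rng: np.random.Generator,
                     grad_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
                     fd_eps: float = 1e-5) -> float:
    """Two-sided gradient penalty ``mean((||grad s(Xhat)|| - 1)^2)``.

    ``Xhat`` interpolates row-wise between ``A`` and ``B`` with one
    uniform coefficient per pair; ``s`` is the sum over output
    coordinates of ``map_fn`` (row-sum of the Jacobian), the standard
    scalarization of a vector-valued map for a WGAN-GP style penalty.

    ``grad_fn(X)``, when given, must return the exact gradient of ``s``
    per row; otherwise a central finite-difference estimate is used.
    """
    Xhat = _interpolates(A, B, rng)
    if grad_fn is not None:
        G = np.asarray(grad_fn(Xhat), dtype=float)
    else:
        G = np.empty_like(Xhat)
        for k in range(Xhat.shape[1]):
            Xp = Xhat.copy()
            Xm = Xhat.copy()
            Xp[:, k] += fd_eps
            Xm[:, k] -= fd_eps
            sp = np.asarray(map_fn(Xp)).sum(axis=1)
            sm = np.asarray(map_fn(Xm)).sum(axis=1)
            G[:, k] = (sp - sm) / (2.0 * fd_eps)
    if not np.all(np.isfinite(G)):
        raise ValueError("gradient_penalty: non-finite gradient at interpolates")
    norms = np.sqrt((G * G).sum(axis=1))
    return float(np.mean((norms - 1.0) ** 2))


def was_gp(i: int, target_private: Sequence[np.ndarray],
           map_fn, A: np.ndarray, B: np.ndarray, rng: np.random.Generator,
           norm: str = "l1", grad_fn=None) -> Tuple[float, float]:
    """Center-alignment across private branches plus gradient penalty.

    Returns ``(l_was, penalty)``; the training loss is their sum.
    """
    l = was_loss(i, target_private, norm)
    gp = gradient_penalty(map_fn, A, B, rng, grad_fn=grad_fn)
    return l, gp


def diff_gp(F_TPi: np.ndarray, F_TS: np.ndarray,
            map_fn, A: np.ndarray, B: np.ndarray, rng: np.random.Generator,
            norm: str = "l1", grad_fn=None) -> Tuple[float, float]:
    """Private-vs-shared center distance plus gradient penalty.

    ``F_TS`` is treated as a constant during training (the shared
    encoder must not be steered by the alignment losses).
    Returns ``(l_diff, penalty)``.
    """
    l = center_distance(F_TPi, F_TS, norm)
    gp = gradient_penalty(map_fn, A, B, rng, grad_fn=grad_fn)
    return l, gp


def smoothed_targets(y: np.ndarray, n_classes: int, epsilon: float) -> np.ndarray:
    """Label-smoothed target distribution: ``1 - eps`` on the true class,
    ``eps / (K - 1)`` elsewhere."""
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("labels must be a 1-d integer vector")
    if np.any((y < 0) | (y >= n_classes)):
        raise ValueError(f"labels outside [0, {n_classes})")
    if not (0.0 <= epsilon < 1.0):
        raise ValueError(f"epsilon must be in [0, 1), got {epsilon}")
    q = np.full((y.shape[0], n_classes), epsilon / (n_classes - 1))
    q[np.arange(y.shape[0]), y] = 1.0 - epsilon
    return q


def label_smoothing_ce(logits: np.ndarray, y: np.ndarray,
                       epsilon: float = 0.1) -> float:
    """Mean label-smoothing cross-entropy, ``-sum_c q(y,c) log p(c)``."""
    logits = np.asarray(logits, dtype=float)
    if logits.ndim != 2 or logits.shape[1] < 2:
        raise ValueError("logits must be (batch, K) with K >= 2")
    q = smoothed_targets(y, logits.shape[1], epsilon)
    z = logits - logits.max(axis=1, keepdims=True)
    log_p = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-(q * log_p).sum(axis=1).mean())


def fusion_weights(w_p: float, w_s: float) -> Tuple[float, float]:
    """Loss-fusion coefficients from the private/shared MMD values.

    The private stream's coefficient is ``w_s / (w_p + w_s)`` and the
    shared stream's is ``w_p / (w_p + w_s)``: the stream whose features
    are already better aligned across domains (smaller MMD) receives
    the *smaller* share of the classification gradient, shifting
    learning capacity to the other stream.  Degenerate ``w_p + w_s = 0``
    falls back to an even split.
    """
    if w_p < 0 or w_s < 0:
        raise ValueError(f"fusion weights must be non-negative, got ({w_p}, {w_s})")
    tot = w_p + w_s
    if tot == 0:
        return 0.5, 0.5
    return w_s / tot, w_p / tot


def alpha_schedule(k: int, total: int) -> float:
    """Warm-up factor ``2 / (1 + exp(-10 k / total)) - 1 == tanh(5 k / total)``.

    Strictly increasing in ``k``, 0 at ``k = 0`` and ``tanh(5) ~ 0.9999``
    at ``k = total``.
    """
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if not (0 <= k <= total):
        raise ValueError(f"step k={k} outside [0, {total}]")
    return float(2.0 / (1.0 + np.exp(-10.0 * k / total)) - 1.0)


def schedule_values(k: int, total: int,
                    alpha_scale: float = 100.0) -> Tuple[float, float, float]:
    """(alpha, beta, gamma) at step ``k``; beta = gamma = alpha / alpha_scale."""
    a = alpha_schedule(k, total)
    return a, a / alpha_scale, a / alpha_scale


@dataclass
class LossBundle:
    """All loss terms, fusion weights and schedule values of one step."""

    l_cl_p: float
    l_cl_s: float
    l_cl: float
    l_mmd: float
    l_was: float
    l_was_gp: float
    l_diff: float
    l_diff_gp: float
    w_p: float
    w_s: float
    coef_p: float
    coef_s: float
    alpha: float
    beta: float
    gamma: float
    epsilon: float
    total: float = float("nan")

    def as_dict(self) -> Dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    def validate(self) -> None:
        if self.l_mmd < 0:
            raise ValueError("l_mmd must be non-negative")
        if self.l_was_gp < self.l_was - 1e-12 or self.l_diff_gp < self.l_diff - 1e-12:
            raise ValueError("gradient penalties must be non-negative")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must lie in [0, 1)")
        if abs(self.coef_p + self.coef_s - 1.0) > 1e-9:
            raise ValueError("fusion coefficients must sum to 1")


def total_loss(bundle: LossBundle) -> float:
    """Total objective ``L_cl + alpha L_mmd + beta L_was-gp + gamma L_diff-gp``
    with ``L_cl = coef_p * L_cl_P + coef_s * L_cl_S``."""
    terms = {
        "l_cl_p": bundle.l_cl_p,
        "l_cl_s": bundle.l_cl_s,
        "l_mmd": bundle.l_mmd,
        "l_was_gp": bundle.l_was_gp,
        "l_diff_gp": bundle.l_diff_gp,
    }
    for name, v in terms.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss term {name} = {v}")
    l_cl = bundle.coef_p * bundle.l_cl_p + bundle.coef_s * bundle.l_cl_s
    return float(l_cl + bundle.alpha * bundle.l_mmd
                 + bundle.beta * bundle.l_was_gp
                 + bundle.gamma * bundle.l_diff_gp)
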