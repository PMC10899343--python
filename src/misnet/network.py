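"""Model architecture: common encoder, private/shared encoders, classifiers.

The network is a family of small fully-connected maps over 310-dim
differential-entropy feature vectors:

* a common encoder ``E_C`` (310-256-128-64) shared by every domain,
* one private encoder ``E_P[i]`` (64-32) per labeled source domain,
* a shared encoder ``E_S`` with the same structure as each private one,
* one private classifier ``C_P[i]`` (32-K) per source and a shared
  classifier ``C_S`` of identical shape.

All hidden layers use LeakyReLU with slope 0.01 and there are no
normalization layers anywhere: the Lipschitz gradient penalty applied
during training assumes the encoders are plain feed-forward maps.

Everything is plain NumPy.  Parameters live in a flat ``{name: array}``
dict (weights stored ``(fan_in, fan_out)``, applied as ``X @ W + b``),
which keeps checkpointing, counting and optimizer bookkeeping trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "ModelSpec",
    "ModelState",
    "build_model",
    "forward_common",
    "forward_private",
    "forward_shared",
    "logits_private",
    "logits_shared",
    "count_parameters",
]


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of the network.

    Parameters
    ----------
    n_sources:
        Number of labeled source domains ``n``; one private encoder and
        one private classifier are created per source.
    n_classes:
        Number of emotion categories ``K``.
    common_widths:
        Layer widths of the common encoder, input first.  The default
        310-256-128-64 matches the standard 62-electrode, 5-band DE
        feature layout.
    branch_widths:
        (input, output) widths of every private/shared encoder; input
        must equal the common encoder output.
    leaky_slope:
        Negative slope of the LeakyReLU used in all hidden layers.
    seed:
        Seed for the deterministic parameter initialization.
    """

    n_sources: int
    n_classes: int
    common_widths: Tuple[int, ...] = (310, 256, 128, 64)
    branch_widths: Tuple[int, int] = (64, 32)
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ValueError(f"n_sources must be >= 1, got {self.n_sources}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if len(self.common_widths) < 2:
            raise ValueError("common_widths needs at least input and output")
        if self.branch_widths[0] != self.common_widths[-1]:
            raise ValueError(
                "branch input width must equal common encoder output: "
                f"{self.branch_widths[0]} != {self.common_widths[-1]}"
            )

    @property
    def input_dim(self) -> int:
        return self.common_widths[0]

    @property
    def latent_dim(self) -> int:
        return self.branch_widths[1]


@dataclass
class ModelState:
    """Parameters of all sub-networks plus the generating spec.

    Parameter naming: ``common.{l}.w/b`` for the common encoder layers,
    ``private.{i}.w/b`` / ``shared.w/b`` for branch encoders and
    ``cls_private.{i}.w/b`` / ``cls_shared.w/b`` for classifiers.
    """

    spec: ModelSpec
    params: Dict[str, np.ndarray]
    training: bool = field(default=False)

    def copy(self) -> "ModelState":
        return ModelState(self.spec, {k: v.copy() for k, v in self.params.items()},
                          self.training)


def _init_affine(rng: np.random.Generator, fan_in: int, fan_out: int):
    # fan-in scaled uniform: U(-1/sqrt(fan_in), 1/sqrt(fan_in)), the
    # standard default for small fully-connected nets
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = rng.uniform(-bound, bound, size=(fan_out,))
    return w, b


def build_model(spec: ModelSpec) -> ModelState:
    """Create a freshly initialized :class:`ModelState`.

    Initialization is deterministic given ``spec.seed``: the same spec
    always yields bit-identical parameters.
    """
    rng = np.random.default_rng(spec.seed)
    params: Dict[str, np.ndarray] = {}
    widths = spec.common_widths
    for l in range(len(widths) - 1):
        w, b = _init_affine(rng, widths[l], widths[l + 1])
        params[f"common.{l}.w"] = w
        params[f"common.{l}.b"] = b
    d_in, d_out = spec.branch_widths
    for i in range(spec.n_sources):
        w, b = _init_affine(rng, d_in, d_out)
        params[f"private.{i}.w"] = w
        params[f"private.{i}.b"] = b
    w, b = _init_affine(rng, d_in, d_out)
    params["shared.w"] = w
    params["shared.b"] = b
    for i in range(spec.n_sources):
        w, b = _init_affine(rng, d_out, spec.n_classes)
        params[f"cls_private.{i}.w"] = w
        params[f"cls_private.{i}.b"] = b
    w, b = _init_affine(rng, d_out, spec.n_classes)
    params["cls_shared.w"] = w
    params["cls_shared.b"] = b
    return ModelState(spec=spec, params=params)


def leaky_relu(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def leaky_relu_grad(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, 1.0, slope)


def _check_width(X: np.ndarray, width: int, what: str) -> None:
    if X.ndim != 2 or X.shape[1] != width:
        raise ValueError(f"{what} expects shape (batch, {width}), got {X.shape}")


def _check_source_index(spec: ModelSpec, i: int) -> None:
    if not (0 <= i < spec.n_sources):
        raise IndexError(
            f"source index {i} out of range for {spec.n_sources} private branches"
        )


def forward_common(state: ModelState, X: np.ndarray) -> np.ndarray:
    """Map 310-dim DE features to 64-dim low-level features X'."""
    _check_width(X, state.spec.input_dim, "forward_common")
    h = X
    for l in range(len(state.spec.common_widths) - 1):
        z = h @ state.params[f"common.{l}.w"] + state.params[f"common.{l}.b"]
        h = leaky_relu(z, state.spec.leaky_slope)
    return h


def forward_private(state: ModelState, i: int, Xp: np.ndarray) -> np.ndarray:
    """Apply private encoder ``E_P[i]`` to low-level features (-> 32-dim)."""
    _check_source_index(state.spec, i)
    _check_width(Xp, state.spec.branch_widths[0], "forward_private")
    z = Xp @ state.params[f"private.{i}.w"] + state.params[f"private.{i}.b"]
    return leaky_relu(z, state.spec.leaky_slope)


def forward_shared(state: ModelState, Xp: np.ndarray) -> np.ndarray:
    """Apply the shared encoder ``E_S`` (same structure as any ``E_P[i]``)."""
    _check_width(Xp, state.spec.branch_widths[0], "forward_shared")
    z = Xp @ state.params["shared.w"] + state.params["shared.b"]
    return leaky_relu(z, state.spec.leaky_slope)


def logits_private(state: ModelState, i: int, F: np.ndarray) -> np.ndarray:
    """Class logits from private classifier ``C_P[i]`` (no softmax)."""
    _check_source_index(state.spec, i)
    _check_width(F, state.spec.branch_widths[1], "logits_private")
    return F @ state.params[f"cls_private.{i}.w"] + state.params[f"cls_private.{i}.b"]


def logits_shared(state: ModelState, F: np.ndarray) -> np.ndarray:
    """Class logits from the shared classifier ``C_S`` (no softmax)."""
    _check_width(F, state.spec.branch_widths[1], "logits_shared")
    return F @ state.params["cls_shared.w"] + state.params["cls_shared.b"]


def count_parameters(state: ModelState) -> int:
    """Total number of trainable scalars across all sub-networks."""
    return int(sum(p.size for p in state.params.values()))


# ---------------------------------------------------------------------------
# cached forward / backward primitives used by the training loop
# ---------------------------------------------------------------------------

def affine_leaky_forward(X, w, b, slope):
    """Affine + LeakyReLU with the pre-activation cached for backward."""
    z = X @ w + b
    return leaky_relu(z, slope), z


def affine_leaky_backward(X, w, z, slope, d_out):
    """Backward through affine+LeakyReLU: returns (dX, dW, db)."""
    dz = d_out * leaky_relu_grad(z, slope)
    return dz @ w.T, X.T @ dz, dz.sum(axis=0)


def common_forward_cached(state: ModelState, X: np.ndarray):
    """Forward through E_C keeping per-layer inputs/pre-activations."""
    slope = state.spec.leaky_slope
    cache: List[Tuple[np.ndarray, np.ndarray]] = []
    h = X
    for l in range(len(state.spec.common_widths) - 1):
        out, z = affine_leaky_forward(h, state.params[f"common.{l}.w"],
                                      state.params[f"common.{l}.b"], slope)
        cache.append((h, z))
        h = out
    return h, cache


def common_backward(state: ModelState, cache, d_out: np.ndarray,
                    grads: Dict[str, np.ndarray]) -> np.ndarray:
    """Accumulate E_C parameter gradients into ``grads``; returns dX."""
    slope = state.spec.leaky_slope
    d = d_out
    for l in reversed(range(len(state.spec.common_widths) - 1)):
        X_in, z = cache[l]
        d, dw, db = affine_leaky_backward(X_in, state.params[f"common.{l}.w"],
                                          z, slope, d)
        grads[f"common.{l}.w"] = grads.get(f"common.{l}.w", 0) + dw
        grads[f"common.{l}.b"] = grads.get(f"common.{l}.b", 0) + db
    return d


def branch_input_grad_of_sum(state: ModelState, name: str, X: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. each input row of the summed branch-encoder output.

    For a branch ``x -> LeakyReLU(W x + b)`` the row-sum of the Jacobian
    at ``x`` is ``W @ a'(z)`` with ``z = W x + b``; the activation's
    derivative is piecewise constant so the expression is exact almost
    everywhere.  Used by the gradient-penalty terms.
    """
    w = state.params[f"{name}.w"]
    b = state.params[f"{name}.b"]
    z = X @ w + b
    d = leaky_relu_grad(z, state.spec.leaky_slope)  # (batch, out)
    return d @ w.T  # (batch, in)
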