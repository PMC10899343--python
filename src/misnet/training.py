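"""Two-phase optimization: supervised pre-training of the common and
shared encoders, then the two-stream loop-iteration domain adaptation.

One *epoch* of the main phase cycles through the ``n`` source domains in
sequence; iteration ``i`` feeds only source ``i`` (labeled) and the
unlabeled target through the network and updates exactly the parameters
on that path — ``E_C``, ``E_P[i]``, ``E_S``, ``C_P[i]``, ``C_S`` — so an
outlier source domain cannot corrupt the other private branches.

All gradients are computed analytically (the model is a stack of affine
+ LeakyReLU layers, so every loss term has a closed-form gradient); the
test suite checks them against finite differences of the value-level
loss functions in :mod:`misnet.losses`.

Gradient-flow conventions (which tensors are treated as constants):

* in the cross-branch center alignment, only branch ``i``'s features
  carry gradient — the other private encoders' outputs are constants;
* in the private-vs-shared alignment, the shared encoder's output is a
  constant (the alignment losses must not steer ``E_S``);
* the fusion weights ``w_p, w_s`` are constants (they modulate the
  classification losses, they are not themselves optimized);
* the gradient-penalty interpolation endpoints are constants drawn from
  the current target low-level batch, so the penalty constrains the
  private encoder only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import DEFeatures
from .losses import (LossBundle, center_distance, fusion_weights,
                     label_smoothing_ce, mmd_linear, schedule_values,
                     smoothed_targets, softmax, total_loss, was_loss)
from .network import (ModelSpec, ModelState, affine_leaky_backward,
                      affine_leaky_forward, build_model, common_backward,
                      common_forward_cached, leaky_relu_grad)

__all__ = ["TrainConfig", "TrainHistory", "Adam", "pretrain", "train",
           "iteration_step", "fit_supervised", "cosine_lr",
           "draw_interpolates", "branch_penalty"]


@dataclass
class TrainConfig:
    """Optimization hyper-parameters.

    Defaults follow the reference recipe: Adam with learning rate 0.01,
    batch size 64, 200 main epochs under cosine annealing, 100
    pre-training epochs, label-smoothing probability 0.1 and
    ``beta = gamma = alpha / 100``.
    """

    lr: float = 0.01
    batch_size: int = 64
    epochs_main: int = 200
    epochs_pretrain: int = 100
    epsilon: float = 0.1
    seed: int = 0
    center_norm: str = "l1"
    alpha_scale: float = 100.0
    beta_scale: Optional[float] = None   # overrides alpha_scale for beta
    gamma_scale: Optional[float] = None  # overrides alpha_scale for gamma
    freeze_common_after_pretrain: bool = False
    batches_per_iteration: Optional[int] = None
    shuffle_sources: bool = False
    use_mmd: bool = True
    use_was_gp: bool = True
    use_diff_gp: bool = True

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size < 2:
            raise ValueError("lr must be positive and batch_size >= 2 "
                             "(the MMD estimator needs paired batches)")
        if self.epochs_main < 1 or self.epochs_pretrain < 0:
            raise ValueError("epoch counts must be positive")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("label-smoothing epsilon must be in [0, 1)")

    @property
    def effective_beta_scale(self) -> float:
        return self.beta_scale if self.beta_scale is not None else self.alpha_scale

    @property
    def effective_gamma_scale(self) -> float:
        return self.gamma_scale if self.gamma_scale is not None else self.alpha_scale


@dataclass
class TrainHistory:
    """Per-step loss records plus the schedule counters."""

    records: List[Dict[str, float]] = field(default_factory=list)
    total_steps: int = 0

    def append(self, epoch: int, source: int, step: int, k: int, lr: float,
               bundle: LossBundle) -> None:
        rec = {"epoch": epoch, "source": source, "step": step, "k": k, "lr": lr}
        rec.update(bundle.as_dict())
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)


class Adam(object):
    """Adam with per-parameter step counts; updates only the parameters
    that received a gradient (the two-stream schedule touches a subset
    each iteration)."""

    def __init__(self, params: Dict[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}
        self.t: Dict[str, int] = {}

    def step(self, grads: Dict[str, np.ndarray], lr: float) -> None:
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(self.params[name])
                self.v[name] = np.zeros_like(self.params[name])
                self.t[name] = 0
            self.t[name] += 1
            t = self.t[name]
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / (1 - self.beta1 ** t)
            vhat = self.v[name] / (1 - self.beta2 ** t)
            self.params[name] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from ``base_lr`` to 0 over ``total_epochs``."""
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / total_epochs))


def _iteration_rng(seed: int, *key: int) -> np.random.Generator:
    # independent, reproducible stream per (phase, epoch, iteration, step)
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                                         *[int(k) for k in key]]))


def _draw(rng: np.random.Generator, n_pool: int, size: int) -> np.ndarray:
    # sample without replacement when the pool allows, else resample
    return rng.choice(n_pool, size=size, replace=n_pool < size)


# ---------------------------------------------------------------------------
# analytic gradient pieces
# ---------------------------------------------------------------------------

def _ce_grads(logits: np.ndarray, y: np.ndarray, epsilon: float):
    """Value and logit-gradient of the mean label-smoothing cross-entropy."""
    p = softmax(logits)
    q = smoothed_targets(y, logits.shape[1], epsilon)
    z = logits - logits.max(axis=1, keepdims=True)
    log_p = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    value = float(-(q * log_p).sum(axis=1).mean())
    return value, (p - q) / logits.shape[0]


def _sign_grad(mu_diff: np.ndarray, norm: str) -> np.ndarray:
    """Gradient of ``||mu_diff||`` w.r.t. ``mu_diff`` for the center norm."""
    if norm == "l1":
        return np.sign(mu_diff)
    nrm = np.sqrt(mu_diff @ mu_diff)
    return mu_diff / nrm if nrm > 0 else np.zeros_like(mu_diff)


def draw_interpolates(Xp_T: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Interpolation points for the gradient penalty: row-wise mixes of
    two independent resamplings of the target low-level batch, one
    uniform coefficient per pair.  The result is treated as constant
    (no gradient flows back to the common encoder)."""
    b = Xp_T.shape[0]
    A = Xp_T[rng.integers(0, b, size=b)]
    B = Xp_T[rng.integers(0, b, size=b)]
    u = rng.uniform(size=(b, 1))
    return u * A + (1.0 - u) * B


def branch_penalty(state: ModelState, name: str, Xhat: np.ndarray,
                   gp_eps: float = 1e-12):
    """Two-sided gradient penalty of branch ``name`` at fixed points
    ``Xhat``, with its analytic weight gradient.

    Returns ``(penalty, dW)``; the bias receives no gradient because the
    activation derivative is piecewise constant.
    """
    b = Xhat.shape[0]
    w = state.params[f"{name}.w"]
    bias = state.params[f"{name}.b"]
    z = Xhat @ w + bias
    D = leaky_relu_grad(z, state.spec.leaky_slope)      # (b, out)
    V = D @ w.T                                         # (b, in): grad of sum
    g = np.sqrt((V * V).sum(axis=1))
    penalty = float(np.mean((g - 1.0) ** 2))
    coef = 2.0 * (g - 1.0) / np.maximum(g, gp_eps) / b  # (b,)
    dW = (V * coef[:, None]).T @ D                      # (in, out)
    return penalty, dW


def iteration_step(state: ModelState, i: int,
                   batch_src: Tuple[np.ndarray, np.ndarray],
                   batch_tgt: np.ndarray,
                   schedule_k: int, schedule_total: int,
                   config: TrainConfig,
                   rng: np.random.Generator,
                   ) -> Tuple[LossBundle, Dict[str, np.ndarray]]:
    """One two-stream optimization step for source ``i``.

    Returns the full :class:`LossBundle` and the analytic gradients of
    the total loss with respect to every parameter updated in this
    iteration.  Pure given the model parameters and the RNG state.
    """
    spec = state.spec
    Xs, y = batch_src
    Xt = np.asarray(batch_tgt, dtype=float)
    Xs = np.asarray(Xs, dtype=float)
    if Xs.shape[0] != Xt.shape[0]:
        raise ValueError("source and target batches must have equal size")
    if Xs.shape[1] != spec.input_dim or Xt.shape[1] != spec.input_dim:
        raise ValueError("batch width does not match the model input width")
    slope = spec.leaky_slope
    grads: Dict[str, np.ndarray] = {}

    # ---- forward --------------------------------------------------------
    Xp_S, cache_S = common_forward_cached(state, Xs)
    Xp_T, cache_T = common_forward_cached(state, Xt)

    wi, bi = state.params[f"private.{i}.w"], state.params[f"private.{i}.b"]
    F_SP, z_SP = affine_leaky_forward(Xp_S, wi, bi, slope)
    F_TP, z_TP = affine_leaky_forward(Xp_T, wi, bi, slope)
    ws_, bs_ = state.params["shared.w"], state.params["shared.b"]
    F_SS, z_SS = affine_leaky_forward(Xp_S, ws_, bs_, slope)
    F_TS, _ = affine_leaky_forward(Xp_T, ws_, bs_, slope)  # constant in losses

    # other private branches on the target batch (constants)
    target_private = []
    for j in range(spec.n_sources):
        if j == i:
            target_private.append(F_TP)
        else:
            Fj, _ = affine_leaky_forward(
                Xp_T, state.params[f"private.{j}.w"],
                state.params[f"private.{j}.b"], slope)
            target_private.append(Fj)

    cwi = state.params[f"cls_private.{i}.w"]
    cbi = state.params[f"cls_private.{i}.b"]
    logits_P = F_SP @ cwi + cbi
    cws = state.params["cls_shared.w"]
    cbs = state.params["cls_shared.b"]
    logits_S = F_SS @ cws + cbs

    # ---- loss values ----------------------------------------------------
    alpha, beta, gamma = schedule_values(schedule_k, schedule_total,
                                         config.alpha_scale)
    beta = alpha / config.effective_beta_scale
    gamma = alpha / config.effective_gamma_scale
    if not config.use_mmd:
        alpha = 0.0
    if not config.use_was_gp:
        beta = 0.0
    if not config.use_diff_gp:
        gamma = 0.0

    l_cl_p, dlogits_P = _ce_grads(logits_P, y, config.epsilon)
    l_cl_s, dlogits_S = _ce_grads(logits_S, y, config.epsilon)

    l_mmd = mmd_linear(F_SP, F_TP)
    w_p = l_mmd                      # Eq. pair: same statistic, detached
    w_s = mmd_linear(F_SS, F_TS)
    coef_p, coef_s = fusion_weights(w_p, w_s)

    l_was = was_loss(i, target_private, config.center_norm) \
        if spec.n_sources > 1 else 0.0
    gp_w, dW_gpw = branch_penalty(state, f"private.{i}",
                                  draw_interpolates(Xp_T, rng))
    l_diff = center_distance(F_TP, F_TS, config.center_norm)
    gp_d, dW_gpd = branch_penalty(state, f"private.{i}",
                                  draw_interpolates(Xp_T, rng))

    bundle = LossBundle(
        l_cl_p=l_cl_p, l_cl_s=l_cl_s,
        l_cl=coef_p * l_cl_p + coef_s * l_cl_s,
        l_mmd=l_mmd, l_was=l_was, l_was_gp=l_was + gp_w,
        l_diff=l_diff, l_diff_gp=l_diff + gp_d,
        w_p=w_p, w_s=w_s, coef_p=coef_p, coef_s=coef_s,
        alpha=alpha, beta=beta, gamma=gamma, epsilon=config.epsilon)
    bundle.total = total_loss(bundle)

    # ---- backward -------------------------------------------------------
    b = Xs.shape[0]
    dlogits_P = coef_p * dlogits_P
    dlogits_S = coef_s * dlogits_S
    grads[f"cls_private.{i}.w"] = F_SP.T @ dlogits_P
    grads[f"cls_private.{i}.b"] = dlogits_P.sum(axis=0)
    grads["cls_shared.w"] = F_SS.T @ dlogits_S
    grads["cls_shared.b"] = dlogits_S.sum(axis=0)

    dF_SP = dlogits_P @ cwi.T
    dF_SS = dlogits_S @ cws.T

    # linear-kernel MMD on the private stream
    mu_d = F_SP.mean(axis=0) - F_TP.mean(axis=0)
    dF_SP = dF_SP + alpha * 2.0 * mu_d / b
    dF_TP = -alpha * 2.0 * mu_d / b * np.ones((b, 1))

    # cross-branch center alignment (only branch i carries gradient)
    if spec.n_sources > 1 and beta != 0.0:
        mu_i = F_TP.mean(axis=0)
        acc = np.zeros(spec.branch_widths[1])
        for j in range(spec.n_sources):
            if j != i:
                acc += _sign_grad(mu_i - target_private[j].mean(axis=0),
                                  config.center_norm)
        dF_TP = dF_TP + beta * acc / b
    # private-vs-shared center alignment (shared side constant)
    if gamma != 0.0:
        dF_TP = dF_TP + gamma * _sign_grad(
            F_TP.mean(axis=0) - F_TS.mean(axis=0), config.center_norm) / b

    # branch encoder i: two streams plus the penalty terms
    dXp_S1, dWi, dbi = affine_leaky_backward(Xp_S, wi, z_SP, slope, dF_SP)
    dXp_T1, dWi2, dbi2 = affine_leaky_backward(Xp_T, wi, z_TP, slope, dF_TP)
    grads[f"private.{i}.w"] = dWi + dWi2 + beta * dW_gpw + gamma * dW_gpd
    grads[f"private.{i}.b"] = dbi + dbi2

    # shared encoder: source classification stream only
    dXp_S2, dWs, dbs = affine_leaky_backward(Xp_S, ws_, z_SS, slope, dF_SS)
    grads["shared.w"] = dWs
    grads["shared.b"] = dbs

    if not config.freeze_common_after_pretrain:
        common_backward(state, cache_S, dXp_S1 + dXp_S2, grads)
        common_backward(state, cache_T, dXp_T1, grads)

    return bundle, grads


# ---------------------------------------------------------------------------
# supervised trunk training (pre-training and the no-adaptation baseline)
# ---------------------------------------------------------------------------

def fit_supervised(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                   config: TrainConfig, epochs: int,
                   seed_offset: int = 0,
                   epsilon: float = 0.0) -> Dict[str, np.ndarray]:
    """Train ``E_C -> E_S -> classifier`` with (optionally smoothed)
    cross-entropy.

    Used for the subject-dependent pre-training phase (plain CE,
    ``epsilon = 0``) and for the pooled-source no-adaptation control
    (which keeps the method's label-smoothed classification loss and
    drops only the adaptation terms).  Returns the trained parameters
    (common, shared and the classifier head).
    """
    state = build_model(ModelSpec(n_sources=1, n_classes=spec.n_classes,
                                  common_widths=spec.common_widths,
                                  branch_widths=spec.branch_widths,
                                  leaky_slope=spec.leaky_slope,
                                  seed=spec.seed))
    params = {k: v for k, v in state.params.items()
              if k.startswith("common.") or k in
              ("shared.w", "shared.b", "cls_shared.w", "cls_shared.b")}
    state.params = params
    opt = Adam(params)
    n = X.shape[0]
    slope = spec.leaky_slope
    for epoch in range(epochs):
        rng = _iteration_rng(config.seed, 1000 + seed_offset, epoch)
        order = rng.permutation(n)
        lr = cosine_lr(config.lr, epoch, epochs)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size < 2:
                continue
            Xb, yb = X[idx], y[idx]
            H, cache = common_forward_cached(state, Xb)
            F, zF = affine_leaky_forward(H, params["shared.w"],
                                         params["shared.b"], slope)
            logits = F @ params["cls_shared.w"] + params["cls_shared.b"]
            _, dlogits = _ce_grads(logits, yb, epsilon)
            grads: Dict[str, np.ndarray] = {
                "cls_shared.w": F.T @ dlogits,
                "cls_shared.b": dlogits.sum(axis=0),
            }
            dF = dlogits @ params["cls_shared.w"].T
            dH, dWs, dbs = affine_leaky_backward(H, params["shared.w"], zF,
                                                 slope, dF)
            grads["shared.w"] = dWs
            grads["shared.b"] = dbs
            common_backward(state, cache, dH, grads)
            opt.step(grads, lr)
    return params


def _stack_sources(sources: Sequence[DEFeatures]):
    for s in sources:
        if s.labels is None:
            raise ValueError("pre-training requires labeled source domains")
    X = np.vstack([s.matrix for s in sources])
    y = np.concatenate([np.asarray(s.labels, dtype=int) for s in sources])
    return X, y


def pretrain(spec: ModelSpec, sources: Sequence[DEFeatures],
             config: TrainConfig) -> Dict[str, np.ndarray]:
    """Subject-dependent pre-training of ``E_C`` and ``E_S``.

    All shuffled source data train the common encoder, the shared
    encoder and a throwaway classifier with plain cross-entropy; only
    the two encoders' weights are returned, the classifier is discarded.
    """
    X, y = _stack_sources(sources)
    params = fit_supervised(spec, X, y, config, config.epochs_pretrain)
    return {k: v.copy() for k, v in params.items()
            if not k.startswith("cls_")}


def train(spec: ModelSpec, sources: Sequence[DEFeatures],
          target: DEFeatures, config: TrainConfig,
          pretrained: Optional[Dict[str, np.ndarray]] = None,
          ) -> Tuple[ModelState, TrainHistory]:
    """Main two-stream loop-iteration adaptation.

    Each of ``epochs_main`` epochs performs one iteration per source
    domain in fixed order; iteration ``i`` draws matched labeled-source
    / unlabeled-target batches and steps Adam on the total loss.  The
    warm-up counter ``k`` advances once per optimizer step; learning
    rate follows cosine annealing per epoch.  Deterministic given
    ``config.seed``.
    """
    n = spec.n_sources
    if len(sources) != n:
        raise ValueError(f"{len(sources)} source domains for spec.n_sources={n}")
    if target.labels is not None:
        raise ValueError("target domain must be unlabeled during training "
                         "(use DEFeatures.unlabeled())")
    for s in sources:
        if s.matrix.shape[1] != spec.input_dim:
            raise ValueError("source feature width does not match the model")
        if s.labels is None:
            raise ValueError("source domains must be labeled")
    if target.matrix.shape[1] != spec.input_dim:
        raise ValueError("target feature width does not match the model")

    state = build_model(spec)
    if pretrained is not None:
        for k_, v in pretrained.items():
            if k_.startswith("cls_"):
                raise ValueError("pretrained weights must not contain "
                                 "classifier members")
            if k_ not in state.params:
                raise KeyError(f"unknown pretrained member {k_}")
            state.params[k_] = v.copy()
    state.training = True

    opt = Adam(state.params)
    bpi = [config.batches_per_iteration or
           max(1, math.ceil(s.n_samples / config.batch_size))
           for s in sources]
    total = config.epochs_main * sum(bpi)
    history = TrainHistory(total_steps=total)
    Xt_pool = target.matrix
    k = 0
    for epoch in range(config.epochs_main):
        lr = cosine_lr(config.lr, epoch, config.epochs_main)
        order = list(range(n))
        if config.shuffle_sources:
            order = list(_iteration_rng(config.seed, 2, epoch).permutation(n))
        for i in order:
            src = sources[i]
            for step in range(bpi[i]):
                rng = _iteration_rng(config.seed, 3, epoch, i, step)
                si = _draw(rng, src.n_samples, config.batch_size)
                ti = _draw(rng, Xt_pool.shape[0], config.batch_size)
                k += 1
                try:
                    bundle, grads = iteration_step(
                        state, i,
                        (src.matrix[si], np.asarray(src.labels, dtype=int)[si]),
                        Xt_pool[ti], k, total, config, rng)
                except FloatingPointError as exc:
                    raise FloatingPointError(
                        f"epoch {epoch}, iteration {i}: {exc}") from exc
                opt.step(grads, lr)
                history.append(epoch, i, step, k, lr, bundle)
    state.training = False
    return state, history
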