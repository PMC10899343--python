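"""Test-time fusion, LOSO protocol, metrics, noise robustness and the
hyper-parameter sweep harness.

Prediction fuses all classifier heads: the softmax outputs of the ``n``
private branches are averaged and the shared branch's softmax is added,
so each row's scores sum to 2 and the argmax picks the consensus class.

The leave-one-subject-out (LOSO) protocol holds each subject out in
turn as the unlabeled target; its labels are used only for scoring,
never during training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import DEFeatures, electrode_normalize
from .losses import softmax
from .network import (ModelSpec, ModelState, forward_common, forward_private,
                      forward_shared, logits_private, logits_shared)
from .training import TrainConfig, TrainHistory, pretrain, train

__all__ = ["MetricsReport", "NoiseConfig", "predict", "compute_metrics",
           "loso", "add_noise", "noise_curve", "sweep", "LosoSummary"]


@dataclass
class MetricsReport:
    """Classification metrics with one-vs-rest macro averaging."""

    accuracy: float
    macro_f1: float
    macro_sensitivity: float
    macro_specificity: float
    confusion: np.ndarray          # K x K counts, rows = truth
    per_class: Dict[str, List[float]]
    n_samples: int
    degenerate_classes: List[int] = field(default_factory=list)

    def as_dict(self) -> Dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "n_samples": self.n_samples,
            "degenerate_classes": self.degenerate_classes,
        }


@dataclass(frozen=True)
class NoiseConfig:
    """Noise coefficients for the robustness curve ``X + K * N(0, 1)``."""

    coefficients: Tuple[float, ...] = (0.0, 0.1, 0.2, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.coefficients):
            raise ValueError("noise coefficients must be non-negative")


def predict(state: ModelState, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Fused class scores and labels for target features.

    ``score = (1/n) * sum_i softmax(C_P[i](E_P[i](X'))) + softmax(C_S(E_S(X')))``
    (each row of scores sums to 2); ties break toward the lowest class
    index.  Returns ``(labels, scores)``.
    """
    for name, p in state.params.items():
        if not np.all(np.isfinite(p)):
            raise ValueError(f"model parameter {name} contains non-finite values")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xp = forward_common(state, X)
    n = state.spec.n_sources
    scores = np.zeros((X.shape[0], state.spec.n_classes))
    for i in range(n):
        Fp = forward_private(state, i, Xp)
        scores += softmax(logits_private(state, i, Fp))
    scores /= n
    Fs = forward_shared(state, Xp)
    scores += softmax(logits_shared(state, Fs))
    return scores.argmax(axis=1), scores


def compute_metrics(pred_labels: np.ndarray, true_labels: np.ndarray,
                    n_classes: int) -> MetricsReport:
    """Confusion matrix plus macro-averaged F1 / sensitivity / specificity.

    Per class (one-vs-rest): sensitivity = TP/(TP+FN), specificity =
    TN/(TN+FP), F1 = 2PR/(P+R).  Classes with a zero denominator
    contribute 0 and are listed in ``degenerate_classes``.
    """
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("prediction and truth must be equal-length, non-empty")
    if np.any((pred < 0) | (pred >= n_classes) | (true < 0) | (true >= n_classes)):
        raise ValueError(f"labels outside [0, {n_classes})")
    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (true, pred), 1)
    total = conf.sum()
    tp = np.diag(conf).astype(float)
    fn = conf.sum(axis=1) - tp
    fp = conf.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def _safe(num, den):
        out = np.zeros_like(num, dtype=float)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        return out, np.where(~ok)[0]

    sens, d1 = _safe(tp, tp + fn)
    spec, d2 = _safe(tn, tn + fp)
    prec, d3 = _safe(tp, tp + fp)
    f1_den = prec + sens
    f1 = np.zeros(n_classes)
    ok = f1_den > 0
    f1[ok] = 2 * prec[ok] * sens[ok] / f1_den[ok]
    degenerate = sorted(set(d1) | set(d2) | set(d3))
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        macro_f1=float(f1.mean()),
        macro_sensitivity=float(sens.mean()),
        macro_specificity=float(spec.mean()),
        confusion=conf,
        per_class={"sensitivity": sens.tolist(), "specificity": spec.tolist(),
                   "precision": prec.tolist(), "f1": f1.tolist()},
        n_samples=int(total),
        degenerate_classes=[int(c) for c in degenerate],
    )


@dataclass
class LosoSummary:
    """Per-fold reports plus the mean/std accuracy summary."""

    reports: List[MetricsReport]
    subject_ids: List[str]
    mean_accuracy: float
    std_accuracy: float           # population (1/N) convention

    @property
    def accuracies(self) -> List[float]:
        return [r.accuracy for r in self.reports]


def _run_fold(spec: ModelSpec, sources: List[DEFeatures],
              target: DEFeatures, config: TrainConfig,
              do_pretrain: bool) -> Tuple[ModelState, TrainHistory]:
    pre = pretrain(spec, sources, config) if do_pretrain else None
    return train(spec, sources, target.unlabeled(), config, pretrained=pre)


def loso(dataset: Sequence[DEFeatures], config: TrainConfig,
         spec_template: Optional[ModelSpec] = None,
         normalize: bool = True, do_pretrain: bool = True) -> LosoSummary:
    """Leave-one-subject-out evaluation over all subjects.

    Each subject in turn becomes the unlabeled target; every other
    subject is a labeled source.  Target labels are used only to score
    the final predictions.  With ``normalize`` each domain is z-scored
    with its own per-column statistics before training.
    """
    if len(dataset) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    classes = {int(np.max(d.labels)) + 1 for d in dataset if d.labels is not None}
    if len(classes) != 1 or any(d.labels is None for d in dataset):
        raise ValueError("all subjects must be labeled with a consistent "
                         "class count")
    n_classes = classes.pop()
    dim = dataset[0].matrix.shape[1]
    reports: List[MetricsReport] = []
    subjects: List[str] = []
    prepared = dataset
    if normalize:
        prepared = [electrode_normalize(d)[0] for d in dataset]
    for held in range(len(prepared)):
        sources = [d for s, d in enumerate(prepared) if s != held]
        target = prepared[held]
        if spec_template is not None:
            spec = dataclasses.replace(spec_template,
                                       n_sources=len(sources),
                                       n_classes=n_classes)
        else:
            spec = ModelSpec(n_sources=len(sources), n_classes=n_classes,
                             common_widths=(dim, 256, 128, 64),
                             seed=config.seed)
        state, _ = _run_fold(spec, sources, target, config, do_pretrain)
        pred, _ = predict(state, target.matrix)
        reports.append(compute_metrics(pred, target.labels, n_classes))
        subjects.append(target.subject_id or f"subject{held}")
    acc = np.array([r.accuracy for r in reports])
    return LosoSummary(reports=reports, subject_ids=subjects,
                       mean_accuracy=float(acc.mean()),
                       std_accuracy=float(acc.std()))


def add_noise(feat: DEFeatures, k_noise: float, seed: int = 0) -> DEFeatures:
    """Additive Gaussian noise ``X + K * N(0, 1)``; labels untouched."""
    if k_noise < 0:
        raise ValueError("noise coefficient must be non-negative")
    if k_noise == 0:
        return feat
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(feat.matrix.shape)
    return replace(feat, matrix=feat.matrix + k_noise * noise)


def noise_curve(state: ModelState, target: DEFeatures,
                noise_cfg: NoiseConfig) -> List[Tuple[float, MetricsReport]]:
    """Evaluate a fixed model on progressively noisier copies of the
    target features."""
    if target.labels is None:
        raise ValueError("noise_curve requires labeled target features")
    out = []
    for j, k in enumerate(noise_cfg.coefficients):
        noisy = add_noise(target, k, seed=noise_cfg.seed + j)
        pred, _ = predict(state, noisy.matrix)
        out.append((float(k), compute_metrics(pred, target.labels,
                                              state.spec.n_classes)))
    return out


def sweep(dataset: Sequence[DEFeatures], beta_scales: Sequence[float],
          gamma_scales: Sequence[float], config: TrainConfig,
          spec_template: Optional[ModelSpec] = None,
          normalize: bool = True):
    """LOSO accuracy grid over auxiliary-loss scale settings.

    ``beta_scales`` / ``gamma_scales`` are divisors of the warm-up
    factor (``beta = alpha / scale``).  Returns a pandas DataFrame with
    rows = beta scales, columns = gamma scales.
    """
    import pandas as pd
    if not beta_scales or not gamma_scales:
        raise ValueError("scale lists must be non-empty")
    grid = np.empty((len(beta_scales), len(gamma_scales)))
    for a, bs in enumerate(beta_scales):
        for b, gs in enumerate(gamma_scales):
            cfg = dataclasses.replace(config, beta_scale=float(bs),
                                      gamma_scale=float(gs))
            grid[a, b] = loso(dataset, cfg, spec_template,
                              normalize=normalize).mean_accuracy
    return pd.DataFrame(grid,
                        index=[f"beta=alpha/{g:g}" for g in beta_scales],
                        columns=[f"gamma=alpha/{g:g}" for g in gamma_scales])
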