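"""Differential-entropy (DE) feature extraction for multichannel EEG.

Pipeline: band-limit and downsample the raw signal, cut it into
non-overlapping 1 s windows, estimate per-electrode band variances from
a Hann-tapered, zero-padded periodogram, and map each band variance
through the Gaussian differential entropy

    DE = 1/2 * log(2 * pi * e * sigma^2)    (natural log, nats)

yielding one row of ``n_electrodes * n_bands`` values per window
(electrode-major: electrode 0's five band values first).  The five
canonical EEG bands are delta 1-3, theta 4-7, alpha 8-13, beta 14-30
and gamma 31-50 Hz, so a 62-electrode montage gives 310-dim rows.

Optional temporal smoothing (moving average or a random-walk linear
dynamical system) and electrode-wise z-scoring prepare the features for
the domain-adaptation network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "RawEEG",
    "BandSpec",
    "DEFeatures",
    "DEFAULT_BANDS",
    "preprocess",
    "window_signal",
    "de_per_window",
    "extract_de_features",
    "smooth_moving_average",
    "smooth_lds",
    "electrode_normalize",
]

#: variance floor applied before the log so silent channels clamp
#: instead of producing -inf
EPS_VAR = 1e-12

DEFAULT_BANDS: Tuple[Tuple[str, float, float], ...] = (
    ("delta", 1.0, 3.0),
    ("theta", 4.0, 7.0),
    ("alpha", 8.0, 13.0),
    ("beta", 14.0, 30.0),
    ("gamma", 31.0, 50.0),
)


@dataclass
class RawEEG:
    """One trial of multichannel EEG: ``signal`` is electrodes x samples (uV)."""

    signal: np.ndarray
    rate: float
    electrode_names: Sequence[str]
    subject_id: str = ""
    session_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-d (electrodes x samples)")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if len(self.electrode_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.electrode_names)} electrode names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(
                f"non-finite values in trial {self.trial_id or '<unnamed>'}"
            )

    @property
    def n_electrodes(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.rate


@dataclass(frozen=True)
class BandSpec:
    """Ordered, non-overlapping frequency bands (name, low Hz, high Hz)."""

    bands: Tuple[Tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        prev_high = -np.inf
        for name, lo, hi in self.bands:
            if lo >= hi:
                raise ValueError(f"band {name}: low {lo} >= high {hi}")
            if lo < prev_high:
                raise ValueError(f"band {name} overlaps or is out of order")
            prev_high = hi

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def names(self) -> List[str]:
        return [b[0] for b in self.bands]


@dataclass
class DEFeatures:
    """A samples x D feature matrix (D = electrodes x bands, nats)."""

    matrix: np.ndarray
    labels: Optional[np.ndarray] = None
    subject_id: str = ""
    session_id: str = ""
    feature_order: str = "electrode-major"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] == 0:
            raise ValueError("feature matrix must be 2-d with at least one row")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.matrix.shape[0],):
                raise ValueError("labels must align with feature rows")
            if np.any(self.labels < 0):
                raise ValueError("labels must be non-negative class indices")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def unlabeled(self) -> "DEFeatures":
        """A view for training on the target domain: labels stripped."""
        return DEFeatures(self.matrix, None, self.subject_id, self.session_id,
                          self.feature_order)


def preprocess(raw: RawEEG, target_rate: float = 200.0,
               low: float = 0.0, high: float = 75.0) -> RawEEG:
    """Downsample to ``target_rate`` and band-limit to ``(low, high)`` Hz.

    A 0 Hz low edge is vacuous, so the default band acts as a 75 Hz
    low-pass.  Polyphase resampling (with its built-in anti-aliasing
    filter) handles the rate change; a zero-phase Butterworth handles
    the band edges, so the signal duration is preserved to one sample.
    """
    if target_rate > raw.rate:
        raise ValueError(
            f"target rate {target_rate} exceeds input rate {raw.rate}")
    nyq = target_rate / 2.0
    if not (0 <= low < high):
        raise ValueError(f"invalid band ({low}, {high})")
    if high >= nyq:
        raise ValueError(
            f"band edge {high} Hz is at or above the Nyquist frequency "
            f"{nyq} Hz of the target rate")
    x = raw.signal
    if target_rate != raw.rate:
        from fractions import Fraction
        frac = Fraction(target_rate / raw.rate).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=1,
                              padtype="line")
    sos = sps.butter(8, high / nyq, btype="low", output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    if low > 0:
        sos_hp = sps.butter(4, low / nyq, btype="high", output="sos")
        x = sps.sosfiltfilt(sos_hp, x, axis=1)
    return replace(raw, signal=np.ascontiguousarray(x), rate=float(target_rate))


def window_signal(raw: RawEEG, window_seconds: float = 1.0,
                  overlap: float = 0.0) -> List[Tuple[float, np.ndarray]]:
    """Cut the signal into non-overlapping windows.

    Returns ``(start_time_seconds, electrodes x window_samples)`` blocks;
    ``floor(duration / window_seconds)`` of them.  A signal shorter than
    one window yields an empty list with a warning.
    """
    if overlap != 0:
        raise NotImplementedError("only non-overlapping windows are supported")
    win = int(round(raw.rate * window_seconds))
    if win < 2:
        raise ValueError("window must contain at least 2 samples")
    n = raw.signal.shape[1] // win
    if n == 0:
        warnings.warn(
            f"signal of {raw.duration:.3f}s shorter than one "
            f"{window_seconds}s window; no features produced", stacklevel=2)
        return []
    return [(k * win / raw.rate, raw.signal[:, k * win:(k + 1) * win])
            for k in range(n)]


_clamp_logged = False


def de_per_window(block: np.ndarray, rate: float, nfft: int = 512,
                  bands: Optional[BandSpec] = None,
                  eps_var: float = EPS_VAR) -> np.ndarray:
    """Differential entropy per electrode and band for one window.

    The band variance is the integral of the Hann-tapered, zero-padded
    periodogram over the band, and ``DE = 1/2 log(2 pi e sigma^2)`` in
    nats.  Output is electrode-major: electrode e's band values occupy
    positions ``e * n_bands ... (e+1) * n_bands - 1``.
    """
    global _clamp_logged
    bands = bands or BandSpec()
    block = np.asarray(block, dtype=float)
    if block.ndim == 1:
        block = block[None, :]
    if nfft < block.shape[1]:
        raise ValueError(f"nfft {nfft} shorter than window {block.shape[1]}")
    freqs, psd = sps.periodogram(block, fs=rate, window="hann", nfft=nfft,
                                 axis=1, detrend=False)
    df = freqs[1] - freqs[0]
    out = np.empty((block.shape[0], len(bands)))
    for b, (_, lo, hi) in enumerate(bands.bands):
        sel = (freqs >= lo) & (freqs <= hi)
        var = psd[:, sel].sum(axis=1) * df
        clamped = var < eps_var
        if np.any(clamped) and not _clamp_logged:
            logger.warning("band variance below %.1e floored (silent channel?)",
                           eps_var)
            _clamp_logged = True
        var = np.maximum(var, eps_var)
        out[:, b] = 0.5 * np.log(2.0 * np.pi * np.e * var)
    return out.reshape(-1)


def extract_de_features(raw: RawEEG, window_seconds: float = 1.0,
                        nfft: int = 512, bands: Optional[BandSpec] = None,
                        smooth: str = "none", smooth_window: int = 5,
                        ) -> DEFeatures:
    """Full raw-to-DE pipeline for one trial.

    ``smooth`` is one of ``"ma"`` (moving average), ``"lds"``
    (linear-dynamical-system smoother) or ``"none"``.
    """
    bands = bands or BandSpec()
    blocks = window_signal(raw, window_seconds)
    if not blocks:
        raise ValueError(
            f"trial {raw.trial_id or '<unnamed>'} shorter than one window")
    rows = [de_per_window(blk, raw.rate, nfft, bands) for _, blk in blocks]
    feat = DEFeatures(np.vstack(rows), subject_id=raw.subject_id,
                      session_id=raw.session_id)
    if smooth == "ma":
        feat = smooth_moving_average(feat, smooth_window)
    elif smooth == "lds":
        feat = smooth_lds(feat)
    elif smooth != "none":
        raise ValueError(f"unknown smoothing method {smooth!r}")
    return feat


def smooth_moving_average(feat: DEFeatures, window: int = 5) -> DEFeatures:
    """Centered moving mean per column with edge truncation.

    At the edges the average runs over however many of the ``window``
    positions fall inside the trial, so the shape is preserved and a
    constant column is unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return replace(feat, matrix=feat.matrix.copy())
    n = feat.n_samples
    if window > n:
        warnings.warn(f"moving-average window {window} exceeds trial length "
                      f"{n}; clipping", stacklevel=2)
        window = n
    half = (window - 1) // 2
    # cumulative-sum trick: mean over [max(0, t-half), min(n, t+window-half))
    cs = np.vstack([np.zeros((1, feat.dim)), np.cumsum(feat.matrix, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (window - half), n)
    out = (cs[hi] - cs[lo]) / (hi - lo)[:, None]
    return replace(feat, matrix=out)


def _estimate_rw_noise(col: np.ndarray) -> Tuple[float, float]:
    """Method-of-moments (q, r) for the random-walk-plus-noise model.

    Uses Var(y_t - y_{t-1}) = q + 2r and Var(y_t - y_{t-2}) = 2q + 2r.
    """
    if col.size < 3:
        return 1.0, 1.0
    v1 = np.var(np.diff(col, 1))
    v2 = np.var(col[2:] - col[:-2])
    q = max(v2 - v1, 1e-8)
    r = max((2 * v1 - v2) / 2.0, 1e-8)
    return float(q), float(r)


def smooth_lds(feat: DEFeatures, q_process: Optional[float] = None,
               r_observe: Optional[float] = None) -> DEFeatures:
    """Fixed-interval smoother under a per-column random-walk model.

    Model: ``x_t = x_{t-1} + w`` (process variance ``q``), ``y_t = x_t + v``
    (observation variance ``r``).  A Kalman forward pass followed by an
    RTS backward pass yields the smoothed state sequence.  When ``q``/``r``
    are omitted they are estimated per column by method of moments from
    the lag-1 and lag-2 difference variances.
    """
    if (q_process is not None and q_process <= 0) or \
       (r_observe is not None and r_observe <= 0):
        raise ValueError("q_process and r_observe must be positive")
    Y = feat.matrix
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite values in features")
    n, d = Y.shape
    out = np.empty_like(Y)
    for j in range(d):
        y = Y[:, j]
        q = q_process if q_process is not None else _estimate_rw_noise(y)[0]
        r = r_observe if r_observe is not None else _estimate_rw_noise(y)[1]
        # Kalman forward
        xf = np.empty(n)
        pf = np.empty(n)   # filtered variance
        xp = np.empty(n)
        pp = np.empty(n)   # one-step predicted variance
        xp[0], pp[0] = y[0], q + r  # diffuse-ish prior centered on first obs
        for t in range(n):
            if t > 0:
                xp[t] = xf[t - 1]
                pp[t] = pf[t - 1] + q
            k = pp[t] / (pp[t] + r)
            xf[t] = xp[t] + k * (y[t] - xp[t])
            pf[t] = (1.0 - k) * pp[t]
        # RTS backward
        xs = np.empty(n)
        xs[-1] = xf[-1]
        for t in range(n - 2, -1, -1):
            c = pf[t] / (pf[t] + q)
            xs[t] = xf[t] + c * (xs[t + 1] - xf[t])
        out[:, j] = xs
    return replace(feat, matrix=out)


def electrode_normalize(feat: DEFeatures,
                        stats: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                        sd_floor: float = 1e-8,
                        ) -> Tuple[DEFeatures, Tuple[np.ndarray, np.ndarray]]:
    """Electrode-wise z-scoring: each feature column to mean 0, sd 1.

    ``stats = (mean, sd)`` may be supplied to reuse statistics computed
    on another split; otherwise they are computed from the input
    (population sd) and returned.  Constant columns are floored to
    ``sd_floor`` and become zero.
    """
    X = feat.matrix
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)  # population (1/N) convention
    else:
        mean, sd = (np.asarray(a, dtype=float) for a in stats)
        if mean.shape != (feat.dim,) or sd.shape != (feat.dim,):
            raise ValueError("normalization stats do not match feature width")
    sd = np.maximum(sd, sd_floor)
    return replace(feat, matrix=(X - mean) / sd), (mean, sd)
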