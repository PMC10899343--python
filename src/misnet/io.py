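"""Readers and writers: MAT feature layouts, named-array containers,
checkpoints and run configuration.

MAT feature files follow the common EEG-emotion layout: one array per
trial named e.g. ``de_LDS1 .. de_LDS15`` shaped ``electrodes x windows
x bands``, plus a label vector with one class per trial.  Both classic
(v7, via :mod:`scipy.io`) and HDF5-backed (v7.3, via :mod:`h5py`) MAT
containers are read transparently.  Three-class label values
``{-1, 0, 1}`` map to ``{0, 1, 2}``; four-class ``{0..3}`` labels pass
through unchanged.

Checkpoints are NumPy ``.npz`` archives (one member per layer) with a
JSON sidecar describing the architecture; round-trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .features import DEFeatures, RawEEG
from .network import ModelSpec, ModelState
from .training import TrainConfig

__all__ = ["read_seed_features", "load_features", "save_features",
           "features_to_csv", "save_checkpoint", "load_checkpoint",
           "RunConfig", "load_config", "save_config", "load_raw",
           "save_bundle", "load_bundle"]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# MAT feature reading
# ---------------------------------------------------------------------------

def _load_mat(path: PathLike) -> Dict[str, np.ndarray]:
    """Read a MAT container, autodetecting v7 vs HDF5-backed v7.3."""
    path = Path(path)
    try:
        from scipy.io import loadmat
        raw = loadmat(str(path))
        return {k: np.asarray(v) for k, v in raw.items()
                if not k.startswith("__")}
    except (NotImplementedError, ValueError):
        # v7.3 (HDF5-backed) files make scipy raise; fall through to h5py
        import h5py
        out: Dict[str, np.ndarray] = {}
        with h5py.File(path, "r") as f:
            for k in f.keys():
                # MATLAB HDF5 stores arrays transposed
                out[k] = np.asarray(f[k]).T
        return out


def _map_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).reshape(-1).astype(int)
    if labels.min() == -1:          # 3-class {-1, 0, 1} convention
        return labels + 1
    return labels


def read_seed_features(path: PathLike, key_pattern: str = "de_LDS{trial}",
                       labels: Optional[Sequence[int]] = None,
                       label_path: Optional[PathLike] = None,
                       subject_id: str = "", session_id: str = "",
                       ) -> List[DEFeatures]:
    """Read per-trial DE feature arrays from a MAT container.

    Each trial array ``electrodes x windows x bands`` is flattened to
    ``windows x (electrodes * bands)`` in electrode-major order.  Trial
    labels come from ``labels`` or from ``label_path`` (a MAT file with
    a ``label`` vector) and are broadcast over each trial's windows.
    """
    data = _load_mat(path)
    if label_path is not None:
        lab = _load_mat(label_path)
        if "label" not in lab:
            raise KeyError(f"label file {label_path} has no 'label' member")
        labels = _map_labels(lab["label"])
    elif labels is not None:
        labels = _map_labels(np.asarray(labels))
    out: List[DEFeatures] = []
    trial = 1
    while True:
        key = key_pattern.format(trial=trial)
        if key not in data:
            if trial == 1:
                raise KeyError(
                    f"no trial arrays matching pattern {key_pattern!r} "
                    f"in {path} (first expected key: {key})")
            break
        arr = np.asarray(data[key], dtype=float)
        if arr.ndim != 3:
            raise ValueError(
                f"trial array {key} must be electrodes x windows x bands, "
                f"got shape {arr.shape}")
        n_el, n_win, n_band = arr.shape
        # electrode-major flattening: electrode e's bands are contiguous
        mat = arr.transpose(1, 0, 2).reshape(n_win, n_el * n_band)
        y = None
        if labels is not None:
            if trial - 1 >= len(labels):
                raise ValueError(f"no label for trial {trial}")
            y = np.full(n_win, int(labels[trial - 1]))
        out.append(DEFeatures(mat, labels=y, subject_id=subject_id,
                              session_id=session_id))
        trial += 1
    return out


# ---------------------------------------------------------------------------
# feature containers
# ---------------------------------------------------------------------------

def save_features(feat: DEFeatures, path: PathLike) -> None:
    """Write a DEFeatures to a named-array container (``.npz``)."""
    members = {"X": feat.matrix,
               "subject": np.array(feat.subject_id),
               "session": np.array(feat.session_id),
               "feature_order": np.array(feat.feature_order)}
    if feat.labels is not None:
        members["y"] = np.asarray(feat.labels)
    np.savez(path, **members)


def load_features(path: PathLike) -> DEFeatures:
    with np.load(path, allow_pickle=False) as z:
        return DEFeatures(z["X"],
                          labels=z["y"] if "y" in z.files else None,
                          subject_id=str(z["subject"]),
                          session_id=str(z["session"]),
                          feature_order=str(z["feature_order"]))


def features_to_csv(feat: DEFeatures, path: PathLike,
                    electrode_names: Optional[Sequence[str]] = None,
                    band_names: Sequence[str] = ("delta", "theta", "alpha",
                                                 "beta", "gamma")) -> None:
    """CSV export with ``electrode_band`` column headers."""
    import pandas as pd
    n_bands = len(band_names)
    if feat.dim % n_bands:
        raise ValueError("feature width is not a multiple of the band count")
    n_el = feat.dim // n_bands
    if electrode_names is None:
        electrode_names = [f"ch{e:02d}" for e in range(n_el)]
    cols = [f"{el}_{b}" for el in electrode_names for b in band_names]
    df = pd.DataFrame(feat.matrix, columns=cols)
    if feat.labels is not None:
        df["label"] = feat.labels
    df.to_csv(path, index=False)


def load_raw(path: PathLike) -> RawEEG:
    """Read a raw-signal container with ``signal``, ``rate``, ``electrodes``."""
    p = Path(path)
    data = _load_mat(p) if p.suffix == ".mat" else dict(np.load(p))
    for member in ("signal", "rate", "electrodes"):
        if member not in data:
            raise KeyError(f"raw container {path} missing member {member!r}")
    names = [str(e) for e in np.asarray(data["electrodes"]).reshape(-1)]
    return RawEEG(signal=np.asarray(data["signal"], dtype=float),
                  rate=float(np.asarray(data["rate"]).reshape(-1)[0]),
                  electrode_names=names)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _ckpt_path(path: PathLike) -> Path:
    path = Path(path)
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def save_checkpoint(state: ModelState, path: PathLike) -> None:
    """Write model parameters (``.npz``) plus a JSON spec sidecar."""
    path = _ckpt_path(path)
    np.savez(path, **state.params)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(state.spec), indent=1))


def load_checkpoint(path: PathLike) -> ModelState:
    path = _ckpt_path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"checkpoint sidecar {sidecar} not found")
    d = json.loads(sidecar.read_text())
    d["common_widths"] = tuple(d["common_widths"])
    d["branch_widths"] = tuple(d["branch_widths"])
    spec = ModelSpec(**d)
    params: Dict[str, np.ndarray] = {}
    with np.load(path, allow_pickle=False) as z:
        for name in z.files:
            arr = z[name]
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"corrupted checkpoint member {name!r}")
            params[name] = arr
    expected = {f"common.{l}.{p}" for l in range(len(spec.common_widths) - 1)
                for p in "wb"}
    expected |= {"shared.w", "shared.b", "cls_shared.w", "cls_shared.b"}
    for i in range(spec.n_sources):
        expected |= {f"private.{i}.w", f"private.{i}.b",
                     f"cls_private.{i}.w", f"cls_private.{i}.b"}
    missing = expected - set(params)
    if missing:
        raise ValueError(f"checkpoint missing members: {sorted(missing)[:3]}")
    return ModelState(spec=spec, params=params)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def save_bundle(bundle, out_dir: PathLike) -> None:
    """Write each domain of a synthetic bundle plus a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for j, s in enumerate(bundle.sources):
        save_features(s, out / f"source{j}.npz")
    save_features(bundle.target, out / "target.npz")
    manifest = {"n_sources": bundle.n_sources,
                "domain_shifts": list(map(float, bundle.domain_shifts)),
                "config": dataclasses.asdict(bundle.config)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_bundle(out_dir: PathLike):
    from .synthetic import DomainBundle, SynthConfig
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    cfg = SynthConfig(**manifest["config"])
    sources = [load_features(out / f"source{j}.npz")
               for j in range(manifest["n_sources"])]
    target = load_features(out / "target.npz")
    return DomainBundle(sources=sources, target=target, config=cfg,
                        domain_shifts=manifest["domain_shifts"])


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat key/value run configuration: optimizer settings plus the
    handful of pipeline switches."""

    train: TrainConfig
    n_classes: int = 3
    smooth: str = "none"
    smooth_window: int = 5

    def as_flat_dict(self) -> Dict:
        d = dataclasses.asdict(self.train)
        d.update(n_classes=self.n_classes, smooth=self.smooth,
                 smooth_window=self.smooth_window)
        return d


_EXTRA_KEYS = {"n_classes", "smooth", "smooth_window"}


def load_config(path: PathLike) -> RunConfig:
    """Read and strictly validate a flat YAML config; unknown keys are
    rejected (typo safety)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key/value document")
    train_fields = {f.name for f in dataclasses.fields(TrainConfig)}
    unknown = set(raw) - train_fields - _EXTRA_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    train = TrainConfig(**{k: v for k, v in raw.items() if k in train_fields})
    extras = {k: raw[k] for k in _EXTRA_KEYS if k in raw}
    return RunConfig(train=train, **extras)


def save_config(cfg: RunConfig, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_flat_dict(),
                                         sort_keys=True))
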