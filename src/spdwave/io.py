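"""Readers, writers and checkpointing.

Supported on-disk formats:

* EDF recordings (read through :mod:`mne`, honoring the header's sampling
  rates and physical scaling);
* the package's array-archive dataset layout (``data.npz`` +
  ``outcomes.csv`` + ``meta.json`` sidecar, see :mod:`spdwave.simulate`);
* outcome tables as CSV with header ``subject_id,outcome`` (categorical
  outcomes are strings, mapped to indices in sorted order);
* model checkpoints as HDF5 (parameters + architecture config + seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .models import ArchitectureConfig, WaveletSPDNet, build_model
from .simulate import load_dataset, save_dataset

__all__ = [
    "read_recordings",
    "read_edf",
    "read_outcomes",
    "save_checkpoint",
    "load_checkpoint",
    "load_dataset",
    "save_dataset",
]


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list]:
    """Read one EDF file; returns ``(channels x samples, fs, channel names)``.

    Channels with heterogeneous sampling rates are not supported.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


def read_recordings(path: str | Path, format: str | None = None):
    """Load recordings from an EDF file or an array-archive directory.

    Returns ``(recordings, fs, metadata)`` where recordings is ``(C, T)``
    for a single EDF or ``(n, C, T)`` for an archive.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "array-archive"
    if format == "edf":
        data, fs, names = read_edf(path)
        return data, fs, {"channel_names": names}
    if format == "array-archive":
        ds = load_dataset(path)
        return ds.recordings, ds.fs, {"outcomes": ds.outcomes}
    raise ValueError(f"unrecognized format {format!r}")


def read_outcomes(path: str | Path) -> tuple[np.ndarray, dict]:
    """Outcome CSV (``subject_id,outcome``) -> (numeric outcomes, mapping).

    String-valued outcomes are mapped to class indices in sorted order; the
    mapping is returned (empty for numeric outcomes).
    """
    df = pd.read_csv(path)
    if not {"subject_id", "outcome"} <= set(df.columns):
        raise ValueError("outcome table needs columns subject_id,outcome")
    df = df.sort_values("subject_id")
    values = df["outcome"]
    if values.dtype == object:
        classes = sorted(values.unique())
        mapping = {c: i for i, c in enumerate(classes)}
        return values.map(mapping).to_numpy(float), mapping
    return values.to_numpy(float), {}


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: WaveletSPDNet, path: str | Path) -> Path:
    """Serialize parameters, architecture config and metadata to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for key, value in model.state().items():
            h5.create_dataset(f"params/{key}", data=value)
        h5.attrs["config"] = json.dumps(model.cfg.to_dict())
        h5.attrs["n_channels"] = model.n_channels
        h5.attrs["fs"] = model.fs
        h5.attrs["seed"] = model.seed
        h5.attrs["trained"] = model.trained
    return path


def _visit_arrays(group, prefix=""):
    out = {}
    for key, item in group.items():
        name = f"{prefix}{key}"
        if isinstance(item, h5py.Group):
            out.update(_visit_arrays(item, prefix=f"{name}/"))
        else:
            out[name] = np.array(item)
    return out


def load_checkpoint(path: str | Path) -> WaveletSPDNet:
    """Rebuild a model from :func:`save_checkpoint` output (bit-exact)."""
    with h5py.File(path, "r") as h5:
        cfg = ArchitectureConfig.from_dict(json.loads(h5.attrs["config"]))
        model = build_model(
            cfg, int(h5.attrs["n_channels"]), float(h5.attrs["fs"]),
            seed=int(h5.attrs["seed"]),
        )
        model.load_state(_visit_arrays(h5["params"]))
        model.trained = bool(h5.attrs["trained"])
    model.eval()
    return model


def load_run_config(path: str | Path) -> dict:
    """YAML run configuration with a versioned schema key."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or cfg.get("schema") != "spdwave-run-v1":
        raise ValueError("run config must be a mapping with schema: spdwave-run-v1")
    return cfg
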