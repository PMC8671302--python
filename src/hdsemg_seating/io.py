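"""File formats: epoch containers with JSON sidecars, map exports.

Each epoch is stored as a NumPy ``.npy`` channel matrix next to a JSON
sidecar carrying the trial key, grid geometry, sampling rate and (for
cleaned epochs) the processing log.  Maps are exported as plain CSV
matrices and optionally as PNG images with the 0-30 uV color convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .core import DifferentialEpoch, ElectrodeGridSpec, MonopolarEpoch, RmsMap, TrialKey

__all__ = [
    "epoch_stem",
    "save_epoch",
    "load_epoch",
    "export_map_csv",
    "export_map_png",
]


def epoch_stem(key: TrialKey) -> str:
    return f"s{key.subject_id:02d}_{key.chair}_{key.side}_t{key.trial_index:02d}"


def save_epoch(epoch: MonopolarEpoch | DifferentialEpoch, out_dir: str | Path) -> Path:
    """Write an epoch as ``<stem>.npy`` + ``<stem>.json`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = epoch_stem(epoch.key)
    npy = out_dir / f"{stem}.npy"
    np.save(npy, epoch.samples)
    sidecar = {
        "kind": "differential" if isinstance(epoch, DifferentialEpoch) else "monopolar",
        "subject": epoch.key.subject_id,
        "chair": epoch.key.chair,
        "side": epoch.key.side,
        "trial_index": epoch.key.trial_index,
        "time_min": epoch.key.time_min,
        "fs_hz": epoch.grid.fs_hz,
        "grid": asdict(epoch.grid),
        "shape": list(epoch.samples.shape),
        "units": "uV",
    }
    if isinstance(epoch, DifferentialEpoch):
        sidecar["processing_log"] = epoch.processing_log
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return npy


def load_epoch(npy_path: str | Path) -> MonopolarEpoch | DifferentialEpoch:
    """Read an epoch written by :func:`save_epoch`."""
    npy_path = Path(npy_path)
    meta = json.loads(npy_path.with_suffix(".json").read_text())
    samples = np.load(npy_path)
    grid = ElectrodeGridSpec(**meta["grid"])
    key = TrialKey(
        subject_id=meta["subject"],
        chair=meta["chair"],
        side=meta["side"],
        trial_index=meta["trial_index"],
    )
    if meta["kind"] == "differential":
        return DifferentialEpoch(
            samples=samples, grid=grid, key=key, processing_log=meta.get("processing_log", [])
        )
    return MonopolarEpoch(samples=samples, grid=grid, key=key)


def export_map_csv(m: RmsMap, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, m.values, delimiter=",", fmt="%.6g")
    return path


def export_map_png(
    m: RmsMap, path: str | Path, vmin: float = 0.0, vmax: float = 30.0
) -> Path:
    """PNG rendering of an RMS map with a fixed 0-30 uV color scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    ny, nx = m.values.shape
    dx, dy = m.pixel_mm
    fig, ax = plt.subplots(figsize=(3, 4))
    im = ax.imshow(
        m.values,
        vmin=vmin,
        vmax=vmax,
        cmap="jet",
        extent=(0, nx * dx, ny * dy, 0),
        interpolation="nearest",
    )
    ax.set_xlabel(f"x (mm)  {m.orientation}")
    ax.set_ylabel("y (mm, caudal)")
    if m.key is not None:
        ax.set_title(
            f"s{m.key.subject_id} {m.key.chair} {m.key.side} t{m.key.trial_index}", fontsize=9
        )
    fig.colorbar(im, ax=ax, label="RMS (uV)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
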