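"""Core domain types for high-density surface EMG (HDsEMG) grid recordings.

The recording setup modelled throughout this package is a pair of 16-row by
8-column electrode grids (10 mm inter-electrode distance) placed over the
lumbar erector spinae muscles, one grid per side of the spine, sampled at
2048 Hz in monopolar mode.  Epochs are 20 s long and acquired every 5 min
during a 55 min playing session, giving 12 trials per session; each subject
sits on a standard stool ("SS") in one session and on an alternative chair
with lumbar support ("A") in the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHAIRS = ("SS", "A")
SIDES = ("L", "R")

#: minutes between consecutive trials
TRIAL_SPACING_MIN = 5


@dataclass(frozen=True)
class ElectrodeGridSpec:
    """Geometry and sampling of one HDsEMG electrode grid."""

    n_rows: int = 16
    n_cols: int = 8
    ied_mm: float = 10.0
    fs_hz: float = 2048.0
    electrode_diameter_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise ValueError("grid needs at least 2 rows for differentiation")
        if self.n_cols < 1:
            raise ValueError("grid needs at least 1 column")
        if self.ied_mm <= 0:
            raise ValueError("inter-electrode distance must be positive")
        if self.fs_hz <= 2 * 400:
            raise ValueError("sampling rate must exceed twice the 400 Hz band edge")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_diff_rows(self) -> int:
        """Rows of the single-differential montage (one fewer than monopolar)."""
        return self.n_rows - 1


@dataclass(frozen=True)
class TrialKey:
    """Identifies one epoch in the crossover design.

    ``time_min`` is determined by the trial index: trials are 5 min apart,
    so trial 1 is at 0 min and trial 12 at 55 min.
    """

    subject_id: int
    chair: str
    side: str
    trial_index: int

    def __post_init__(self) -> None:
        if self.chair not in CHAIRS:
            raise ValueError(f"chair must be one of {CHAIRS}, got {self.chair!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if not 1 <= self.trial_index <= 12:
            raise ValueError("trial_index must be in 1..12")

    @property
    def time_min(self) -> int:
        return TRIAL_SPACING_MIN * (self.trial_index - 1)


@dataclass
class MonopolarEpoch:
    """Raw monopolar signals of one grid for one trial.

    samples: array of shape (n_rows, n_cols, n_samples) in microvolts.
    """

    samples: np.ndarray
    grid: ElectrodeGridSpec
    key: TrialKey

    def __post_init__(self) -> None:
        s = np.asarray(self.samples)
        if s.ndim != 3 or s.shape[:2] != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"samples must have shape ({self.grid.n_rows}, {self.grid.n_cols}, n); "
                f"got {s.shape}"
            )
        self.samples = s

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.grid.fs_hz


@dataclass
class DifferentialEpoch:
    """Single-differential signals: adjacent-row differences along the columns
    (approximately the muscle-fiber direction), which cancels common-mode
    components such as the ECG.

    samples: array of shape (n_rows - 1, n_cols, n_samples) in microvolts.
    """

    samples: np.ndarray
    grid: ElectrodeGridSpec
    key: TrialKey
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples)
        if s.ndim != 3 or s.shape[:2] != (self.grid.n_diff_rows, self.grid.n_cols):
            raise ValueError(
                f"samples must have shape ({self.grid.n_diff_rows}, {self.grid.n_cols}, n); "
                f"got {s.shape}"
            )
        self.samples = s

    def log(self, entry: str) -> None:
        self.processing_log.append(entry)


def medial_lateral_orientation(side: str) -> str:
    """Anatomical labelling of the column axis for a given side.

    Column C1 of the right grid is the medial column (closest to the spine);
    on the left grid C8 is medial.  The map x axis runs C1 -> C8.
    """
    if side == "R":
        return "x: medial (C1) -> lateral (C8)"
    if side == "L":
        return "x: lateral (C1) -> medial (C8)"
    raise ValueError(f"side must be 'L' or 'R', got {side!r}")


@dataclass
class RmsMap:
    """Topographical image of per-channel RMS amplitude (microvolts).

    Native maps are (n_rows-1) x n_cols; interpolated maps are finer.
    ``pixel_mm`` is the (dx, dy) pixel pitch; the origin is the top-left
    pixel centre, x increasing along columns C1->C8, y increasing caudally
    along rows.
    """

    values: np.ndarray
    pixel_mm: tuple[float, float]
    key: TrialKey | None = None
    orientation: str = ""
    interpolated: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("RMS map must be a 2-D image")
        if np.any(v < 0):
            raise ValueError("RMS values cannot be negative")
        self.values = v
        if not self.orientation and self.key is not None:
            self.orientation = medial_lateral_orientation(self.key.side)

    @property
    def spatial_mean(self) -> float:
        return float(self.values.mean())

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate vectors of pixel centres in mm."""
        dx, dy = self.pixel_mm
        ny, nx = self.values.shape
        return np.arange(nx) * dx, np.arange(ny) * dy


@dataclass
class RegionOfActivity:
    """Segmented region of activity (ROA) of an RMS map.

    ``rms_roa`` is the spatial mean of the map inside the mask.  When the
    map's spatial mean does not exceed the noise level, the whole map is
    used (``used_full_map``).
    """

    mask: np.ndarray
    used_full_map: bool
    rms_roa: float
    centroid_mm: tuple[float, float]
    noise_level: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if not self.used_full_map and not m.any():
            raise ValueError("ROA mask is empty")
        if self.rms_roa < 0:
            raise ValueError("rms_roa cannot be negative")
        self.mask = m

    @property
    def area_pixels(self) -> int:
        return int(self.mask.sum())
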