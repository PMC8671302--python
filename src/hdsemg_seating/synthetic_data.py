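"""Synthetic HDsEMG cohorts with known ground truth.

The generator emulates the study conditions of a two-chair crossover
experiment on 16 seated pianists: per subject, 2 sessions (standard stool
"SS" vs. lumbar-support chair "A") x 2 grids (left/right lumbar erector
spinae) x 12 trials of 20 s at 2048 Hz.  Each monopolar epoch is built from

* an EMG-like activity term: per-differential-channel white Gaussian noise
  band-limited to 20-400 Hz, spatially shaped by a smooth elliptical
  amplitude bump and accumulated along the grid rows so that the
  single-differential montage recovers exactly the intended channels;
* an ECG-like artifact added identically to every electrode of the grid
  (common mode, so it cancels in the differential montage);
* 50 Hz interference with 10 harmonics (amplitudes decaying as 1/k) whose
  per-electrode coupling gain varies, so a residual survives
  differentiation, as in real recordings;
* independent white sensor noise per electrode.

The chair effect is injected multiplicatively on the activity amplitude of
A-chair sessions, with between-subject heterogeneity; trial-to-trial
variation is lognormal.  ``simulate_rms_table`` draws the resulting
region-of-activity RMS values directly at the amplitude level (no signal
synthesis) using the same hierarchy of random factors; it is the fast path
for statistical calibration studies that need many replicate cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import fft as _fft
from scipy import signal as _signal

from .core import CHAIRS, SIDES, ElectrodeGridSpec, MonopolarEpoch, TrialKey

__all__ = [
    "ActivityGroundTruth",
    "CohortConfig",
    "make_activity_truth",
    "simulate_trial",
    "simulate_cohort",
    "simulate_rms_table",
    "simulate_questionnaires",
]

#: sqrt(2): RMS ratio between a difference of two independent equal-RMS
#: noises and either one alone.
_SQRT2 = math.sqrt(2.0)


@dataclass
class ActivityGroundTruth:
    """Ground-truth description of one epoch's muscle activity.

    ``amplitude_map`` holds the target RMS (microvolts) of every
    single-differential channel, shape (n_rows - 1, n_cols).
    """

    amplitude_map: np.ndarray
    roa_mask_true: np.ndarray
    center_true_mm: tuple[float, float]
    chair_scale: float = 1.0
    burst_params: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitude_map, dtype=float)
        if np.any(a < 0):
            raise ValueError("amplitude map cannot contain negative values")
        if self.chair_scale <= 0:
            raise ValueError("chair_scale must be positive")
        m = np.asarray(self.roa_mask_true, dtype=bool)
        if m.shape != a.shape:
            raise ValueError("ground-truth mask must match the amplitude map shape")
        self.amplitude_map = a
        self.roa_mask_true = m

    def scaled(self, s: float) -> "ActivityGroundTruth":
        """Return a copy with amplitudes scaled by ``s``.

        The true region is a property of the activity geometry (where the
        muscle is active relative to background), so the mask is kept
        fixed under overall amplitude scaling -- matching the behaviour of
        contrast-based segmentation downstream.
        """
        return replace(
            self,
            amplitude_map=self.amplitude_map * s,
            chair_scale=self.chair_scale * s,
        )

    @property
    def true_roa_mean(self) -> float:
        """Spatial mean of the amplitude map inside the true mask (microvolts)."""
        if self.roa_mask_true.any():
            return float(self.amplitude_map[self.roa_mask_true].mean())
        return float(self.amplitude_map.mean())


def make_activity_truth(
    grid: ElectrodeGridSpec,
    side: str = "R",
    peak_uv: float = 16.0,
    background_uv: float = 4.5,
    sigma_mm: tuple[float, float] = (20.0, 45.0),
    center_mm: tuple[float, float] | None = None,
    iso_level_uv: float = 5.0,
    burst_params: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> ActivityGroundTruth:
    """Elliptical Gaussian activity bump on a uniform background.

    The bump is placed medially (near the spine): column C1 is medial on the
    right grid and C8 on the left, so the default centre sits 15 mm from the
    medial edge and halfway down the rows.  ``sigma_mm`` is (across-columns,
    along-rows); the region is elongated along the fiber direction.

    The true region of activity is the elevated phase of the two-means
    (ISODATA) partition of the amplitude map -- the region a converged
    two-phase piecewise-constant segmentation describes, and invariant
    under overall amplitude scaling.  A smooth bump has no unique boundary;
    any fixed iso-level would tie the "true" region to the arbitrary
    absolute scale of the map.  For contrast-free maps the ``iso_level_uv``
    threshold is used instead.
    """
    from skimage.filters import threshold_isodata

    ny, nx = grid.n_diff_rows, grid.n_cols
    ied = grid.ied_mm
    if center_mm is None:
        x0 = 15.0 if side == "R" else (nx - 1) * ied - 15.0
        y0 = (ny - 1) * ied / 2.0
    else:
        x0, y0 = center_mm
    x = np.arange(nx) * ied
    y = np.arange(ny) * ied
    xx, yy = np.meshgrid(x, y)
    sx, sy = sigma_mm
    bump = np.exp(-(((xx - x0) ** 2) / (2 * sx**2) + ((yy - y0) ** 2) / (2 * sy**2)))
    amp = background_uv + (peak_uv - background_uv) * bump
    if peak_uv > background_uv:
        mask = amp >= threshold_isodata(amp)
    else:
        mask = amp >= iso_level_uv
    return ActivityGroundTruth(
        amplitude_map=amp,
        roa_mask_true=mask,
        center_true_mm=(x0, y0),
        burst_params=burst_params,
    )


def _bandlimited_unit_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float
) -> np.ndarray:
    """Stationary Gaussian noise band-limited to 20-400 Hz, unit RMS.

    Synthesized spectrally: independent complex-Gaussian spectrum bins
    shaped by the magnitude response of a 4th-order Butterworth band-pass,
    which gives exactly the power spectrum of white noise passed through
    that filter.  Each channel is normalized to unit realized RMS.
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    b, a = _signal.butter(4, [20.0, 400.0], btype="bandpass", fs=fs)
    _, h = _signal.freqz(b, a, worN=2 * np.pi * freqs / fs)
    mag = np.abs(h).astype(np.float32)
    spec_shape = shape[:-1] + (freqs.size,)
    spec = rng.standard_normal(spec_shape, dtype=np.float32) + 1j * rng.standard_normal(
        spec_shape, dtype=np.float32
    )
    spec = spec.astype(np.complex64) * mag
    x = _fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt(np.mean(np.square(x), axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-12)


def _burst_envelope(
    rng: np.random.Generator,
    n: int,
    fs: float,
    duration_ms: tuple[float, float],
    rate_per_s: tuple[float, float],
) -> np.ndarray:
    """On/off envelope of bursts with uniform durations and repetition rate."""
    env = np.zeros(n, dtype=np.float32)
    rate = rng.uniform(*rate_per_s)
    t = rng.uniform(0, 1.0 / rate)
    while t * fs < n:
        dur = rng.uniform(*duration_ms) / 1000.0
        i0 = int(t * fs)
        i1 = min(n, int((t + dur) * fs))
        env[i0:i1] = 1.0
        t += 1.0 / rate
    if not env.any():  # degenerate epoch shorter than one burst period
        env[:] = 1.0
    return env


def _ecg_waveform(n: int, fs: float, peak_uv: float, rng: np.random.Generator) -> np.ndarray:
    """Periodic QRS-like artifact: Ricker pulses at ~1.2 Hz, random phase."""
    f_hr = 1.2
    width_s = 0.025
    t = np.arange(n) / fs + rng.uniform(0, 1 / f_hr)
    phase = np.mod(t, 1.0 / f_hr) - 0.5 / f_hr
    u = phase / width_s
    return (peak_uv * (1 - u**2) * np.exp(-(u**2) / 2)).astype(np.float32)


def _interference_waveform(
    n: int,
    fs: float,
    base_uv: float,
    rng: np.random.Generator,
    base_hz: float = 50.0,
    n_harmonics: int = 10,
) -> np.ndarray:
    """Mains interference: harmonics k = 1..10 with amplitude base_uv / k."""
    t = np.arange(n, dtype=np.float32) / fs
    w = np.zeros(n, dtype=np.float32)
    for k in range(1, n_harmonics + 1):
        f = k * base_hz
        if f >= fs / 2:
            break
        phi = rng.uniform(0, 2 * np.pi)
        w += (base_uv / k) * np.sin(2 * np.pi * f * t + phi, dtype=np.float32)
    return w


def simulate_trial(
    grid: ElectrodeGridSpec,
    truth: ActivityGroundTruth,
    *,
    electrode_noise_uv: float = 2.6 / _SQRT2,
    interference_uv: float = 20.0,
    interference_gain_cv: float = 0.3,
    ecg_uv: float = 80.0,
    epoch_s: float = 20.0,
    seed: int,
    key: TrialKey | None = None,
) -> MonopolarEpoch:
    """Synthesize one monopolar epoch for one grid.

    The activity is generated per differential channel (unit-RMS band-limited
    noise scaled to ``truth.amplitude_map``) and cumulatively summed along
    the rows, so the single-differential derivation returns exactly the
    intended channels.  ``electrode_noise_uv`` is the white-noise RMS of each
    monopolar electrode; a differential channel therefore carries a noise
    floor of sqrt(2) times that value.
    """
    for name, v in [
        ("electrode_noise_uv", electrode_noise_uv),
        ("interference_uv", interference_uv),
        ("ecg_uv", ecg_uv),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    amp = truth.amplitude_map
    if amp.shape != (grid.n_diff_rows, grid.n_cols):
        raise ValueError(
            f"amplitude map shape {amp.shape} does not match grid "
            f"({grid.n_diff_rows}, {grid.n_cols})"
        )
    rng = np.random.default_rng(seed)
    n = int(round(epoch_s * grid.fs_hz))
    fs = grid.fs_hz

    d = _bandlimited_unit_noise(rng, (grid.n_diff_rows, grid.n_cols, n), fs)
    if truth.burst_params is not None:
        dur, rate = truth.burst_params
        env = _burst_envelope(rng, n, fs, dur, rate)
        d = d * env
        rms = np.sqrt(np.mean(np.square(d), axis=-1, keepdims=True))
        d = d / np.maximum(rms, 1e-12)
    d = d * amp[:, :, None].astype(np.float32)

    # integrate along rows: mono[r+1] - mono[r] == d[r]
    mono = np.concatenate(
        [np.zeros((1, grid.n_cols, n), dtype=np.float32), np.cumsum(d, axis=0)], axis=0
    )

    # each component is always drawn (even at zero amplitude) so that the
    # random stream, and hence the realization of every other component, is
    # identical across configurations that differ only in one level
    mono += _ecg_waveform(n, fs, ecg_uv, rng)[None, None, :]
    w = _interference_waveform(n, fs, interference_uv, rng)
    gains = 1.0 + interference_gain_cv * rng.standard_normal(
        (grid.n_rows, grid.n_cols), dtype=np.float32
    )
    mono += gains[:, :, None] * w[None, None, :]
    mono += electrode_noise_uv * rng.standard_normal(mono.shape, dtype=np.float32)

    if key is None:
        key = TrialKey(subject_id=1, chair="SS", side="L", trial_index=1)
    return MonopolarEpoch(samples=mono, grid=grid, key=key)


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults reproduce the crossover design: 16 subjects, 12 trials of 20 s
    per session, 5 min apart; differential noise floor 2.6 uV_RMS (the mean
    baseline of resting maps); mean chair-induced RMS reduction of 30% on
    the left and 35% on the right, with between-subject SD matching the
    large spread seen across real subjects.
    """

    n_subjects: int = 16
    n_trials: int = 12
    epoch_s: float = 20.0
    trial_spacing_min: float = 5.0
    grid: ElectrodeGridSpec = field(default_factory=ElectrodeGridSpec)
    #: baseline noise of a *differential* channel, uV_RMS (electrode noise
    #: is this divided by sqrt(2))
    noise_rms_uv: float = 2.6
    interference_uv: float = 20.0
    ecg_uv: float = 80.0
    #: mean percent RMS reduction on the A-chair, (left, right)
    chair_effect_pct: tuple[float, float] = (30.0, 35.0)
    #: between-subject SD of the chair effect, percent points
    subject_effect_sd_pct: float = 15.0
    #: lognormal sigma of the per-subject overall amplitude scale
    subject_scale_sigma: float = 0.12
    #: lognormal sigma of the per-epoch amplitude jitter
    trial_jitter_sigma: float = 0.08
    peak_uv: float = 16.0
    background_uv: float = 4.5
    #: multiplicative amplitude gain of the right side over the left
    right_side_gain: float = 1.15
    iso_level_uv: float = 5.0
    bursts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials")
        if self.n_subjects < 1:
            raise ValueError("need at least 1 subject")
        for name in ("noise_rms_uv", "interference_uv", "ecg_uv", "peak_uv", "background_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _cohort_factors(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-(subject, side) random factors shared by both simulation paths.

    Returns one row per subject and side with the overall amplitude scale
    (lognormal, mean 1) and the subject's chair effect (normal around the
    configured side mean, clipped to keep the A-chair scale positive).
    """
    rows = []
    for subject in range(1, cfg.n_subjects + 1):
        scale = float(
            np.exp(rng.normal(-0.5 * cfg.subject_scale_sigma**2, cfg.subject_scale_sigma))
        )
        for side, mean_eff in zip(SIDES, cfg.chair_effect_pct):
            eff = float(np.clip(rng.normal(mean_eff, cfg.subject_effect_sd_pct), -60.0, 90.0))
            side_gain = cfg.right_side_gain if side == "R" else 1.0
            rows.append(
                {
                    "subject": subject,
                    "side": side,
                    "amplitude_scale": scale * side_gain,
                    "chair_effect_pct": eff,
                }
            )
    return pd.DataFrame(rows)


def _trial_jitter(cfg: CohortConfig, rng: np.random.Generator) -> float:
    return float(np.exp(rng.normal(-0.5 * cfg.trial_jitter_sigma**2, cfg.trial_jitter_sigma)))


def simulate_cohort(
    cfg: CohortConfig,
) -> Iterator[tuple[TrialKey, MonopolarEpoch, ActivityGroundTruth]]:
    """Yield every epoch of the crossover design, with its ground truth.

    Epochs are yielded lazily (a full cohort holds ~770 20-s 128-channel
    matrices and should be processed in a streaming fashion).  Iteration
    order is subject -> side -> chair -> trial and is deterministic for a
    fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    factors = _cohort_factors(cfg, rng).set_index(["subject", "side"])
    burst_params = ((100.0, 390.0), (1.5, 2.5)) if cfg.bursts else None
    for subject in range(1, cfg.n_subjects + 1):
        for side in SIDES:
            base = make_activity_truth(
                cfg.grid,
                side=side,
                peak_uv=cfg.peak_uv,
                background_uv=cfg.background_uv,
                iso_level_uv=cfg.iso_level_uv,
                burst_params=burst_params,
            )
            row = factors.loc[(subject, side)]
            for chair in CHAIRS:
                chair_scale = (
                    1.0 if chair == "SS" else 1.0 - row["chair_effect_pct"] / 100.0
                )
                for trial in range(1, cfg.n_trials + 1):
                    jit = _trial_jitter(cfg, rng)
                    truth = base.scaled(row["amplitude_scale"] * chair_scale * jit)
                    seed = int(rng.integers(0, 2**31 - 1))
                    key = TrialKey(subject, chair, side, trial)
                    epoch = simulate_trial(
                        cfg.grid,
                        truth,
                        electrode_noise_uv=cfg.noise_rms_uv / _SQRT2,
                        interference_uv=cfg.interference_uv,
                        ecg_uv=cfg.ecg_uv,
                        epoch_s=cfg.epoch_s,
                        seed=seed,
                        key=key,
                    )
                    yield key, epoch, truth


class _MeasurementModel:
    """Noiseless emulation of the mapping stage for one activity geometry.

    The contrast-based segmentation commutes with amplitude scaling, so its
    mask can be computed once on the noiseless measured map (activity plus
    noise floor in quadrature) and reused at every scale.  A trial with
    overall activity scale ``s`` then measures

    * spatial mean  = mean over all pixels of hypot(s * amp, noise_floor)
    * RMS_ROA       = mean over the mask pixels of the same quantity,
                      unless the spatial mean falls at or below the
                      reliability threshold, in which case the whole map is
                      used (the full-map fallback of the real pipeline).
    """

    def __init__(self, truth: ActivityGroundTruth, cfg: CohortConfig) -> None:
        from .core import RmsMap
        from .mapping import interpolate_map, segment_roa

        self.amp = truth.amplitude_map
        self.noise = cfg.noise_rms_uv
        self.level = cfg.iso_level_uv
        meas = np.hypot(self.amp, self.noise)
        m = RmsMap(values=meas, pixel_mm=(cfg.grid.ied_mm, cfg.grid.ied_mm))
        fine = interpolate_map(m, factor=15)
        roa = segment_roa(fine, noise_level=self.level)
        # sample the fine mask at the native pixel centres
        self.mask = roa.mask[::15, ::15]
        if not self.mask.any():
            self.mask = np.ones_like(self.amp, dtype=bool)

    def measure(self, s: float) -> tuple[float, bool]:
        meas = np.hypot(s * self.amp, self.noise)
        spatial = float(meas.mean())
        if spatial > self.level:
            return float(meas[self.mask].mean()), False
        return spatial, True


def simulate_rms_table(cfg: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw region-of-activity RMS values directly at the amplitude level.

    Fast path for calibration studies that need many replicate cohorts: it
    uses the same hierarchy of random factors as :func:`simulate_cohort`
    and replaces the signal synthesis and mapping stages by their noiseless
    measurement model (:class:`_MeasurementModel`), which reproduces the
    noise-floor attenuation, the segmentation-mask concentration and the
    full-map fallback of the full pipeline.  A small multiplicative
    estimator uncertainty is added (the RMS of a 20 s, ~380 Hz-bandwidth
    signal has a relative standard error below 1%).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    factors = _cohort_factors(cfg, rng)
    models = {
        side: _MeasurementModel(
            make_activity_truth(
                cfg.grid,
                side=side,
                peak_uv=cfg.peak_uv,
                background_uv=cfg.background_uv,
                iso_level_uv=cfg.iso_level_uv,
            ),
            cfg,
        )
        for side in SIDES
    }
    est_rel_sd = 0.006
    rows = []
    for _, f in factors.iterrows():
        model = models[f["side"]]
        for chair in CHAIRS:
            chair_scale = 1.0 if chair == "SS" else 1.0 - f["chair_effect_pct"] / 100.0
            for trial in range(1, cfg.n_trials + 1):
                jit = _trial_jitter(cfg, rng)
                s = f["amplitude_scale"] * chair_scale * jit
                rms, fallback = model.measure(s)
                rms *= 1.0 + est_rel_sd * rng.standard_normal()
                rows.append(
                    {
                        "subject": int(f["subject"]),
                        "chair": chair,
                        "side": f["side"],
                        "trial_index": trial,
                        "time_min": cfg.trial_spacing_min * (trial - 1),
                        "rms_roa": rms,
                        "used_full_map": fallback,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# questionnaires
# ---------------------------------------------------------------------------

#: (mean_A, sd_A, mean_SS, sd_SS) per comfort statement; the "like" row uses
#: the group means reported for the real cohort, the rest encode the mild
#: positive trend toward the A-chair.
HZC_ITEM_STATS: dict[str, tuple[float, float, float, float]] = {
    "I feel relaxed": (5.8, 1.5, 5.4, 1.5),
    "I feel refreshed": (5.6, 1.5, 5.3, 1.5),
    "The chair feels soft": (5.5, 1.5, 5.2, 1.5),
    "I like the chair": (7.27, 1.38, 5.00, 0.23),
    "The chair is roomy": (5.7, 1.5, 5.5, 1.5),
    "I feel restful": (5.2, 1.5, 5.5, 1.5),
    "The chair looks nice": (6.0, 1.5, 5.5, 1.5),
}

HZD_ITEM_STATS: dict[str, tuple[float, float, float, float]] = {
    "I have sore muscles": (2.2, 1.5, 2.5, 1.5),
    "I feel heavy legs": (2.0, 1.5, 2.3, 1.5),
    "I feel uneven pressure": (2.3, 1.5, 2.5, 1.5),
    "I feel stiff": (2.2, 1.5, 2.6, 1.5),
    "I feel restless": (2.1, 1.5, 2.4, 1.5),
    "I feel tired": (2.4, 1.5, 2.7, 1.5),
    "I feel cramped": (2.19, 2.11, 1.06, 0.25),
    "I feel numb": (2.00, 1.37, 2.88, 1.86),
    "I feel pain": (1.8, 1.3, 2.1, 1.3),
}

#: General Comfort Rating: (mean_A, mean_SS, sd); real modes were 3 vs 5.
GCR_STATS = (3.0, 5.0, 1.0)

#: Body-part discomfort baseline mean/sd and the extra mean discomfort of
#: the stool (0.5 points on the 0-10 range, as observed on average).
BPD_STATS = (1.0, 1.2, 0.5)


def simulate_questionnaires(
    n_subjects: int = 16,
    seed: int = 0,
    effect: str = "paper-like",
    body_parts: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Integer questionnaire responses for every subject-session.

    ``effect='paper-like'`` uses the per-item group statistics above;
    ``effect='none'`` equalizes the chair means (for type-I calibration).
    Returns a long table with columns (subject, chair, instrument, item,
    score); scores are rounded and clipped to each scale's range.
    """
    if effect not in ("paper-like", "none"):
        raise ValueError("effect must be 'paper-like' or 'none'")
    from .questionnaires import BPD_BODY_PARTS  # avoid import cycle at module load

    parts = body_parts if body_parts is not None else BPD_BODY_PARTS
    rng = np.random.default_rng(seed)
    rows = []

    def draw(mean: float, sd: float, lo: int, hi: int) -> int:
        return int(np.clip(round(rng.normal(mean, sd)), lo, hi))

    for subject in range(1, n_subjects + 1):
        for chair in CHAIRS:
            a_side = chair == "A"
            m_gcr = GCR_STATS[0] if a_side else GCR_STATS[1]
            if effect == "none":
                m_gcr = np.mean(GCR_STATS[:2])
            rows.append(
                {
                    "subject": subject,
                    "chair": chair,
                    "instrument": "GCR",
                    "item": "general comfort",
                    "score": draw(m_gcr, GCR_STATS[2], 1, 10),
                }
            )
            for inst, stats in (("HZc", HZC_ITEM_STATS), ("HZd", HZD_ITEM_STATS)):
                for item, (ma, sa, ms, ss_) in stats.items():
                    if effect == "none":
                        ma = ms = (ma + ms) / 2
                        sa = ss_ = (sa + ss_) / 2
                    m, s = (ma, sa) if a_side else (ms, ss_)
                    rows.append(
                        {
                            "subject": subject,
                            "chair": chair,
                            "instrument": inst,
                            "item": item,
                            "score": draw(m, s, 1, 10),
                        }
                    )
            base_m, base_sd, ss_extra = BPD_STATS
            for part in parts:
                m = base_m if (a_side or effect == "none") else base_m + ss_extra
                rows.append(
                    {
                        "subject": subject,
                        "chair": chair,
                        "instrument": "BPD",
                        "item": part,
                        "score": draw(m, base_sd, 0, 10),
                    }
                )
    return pd.DataFrame(rows)
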