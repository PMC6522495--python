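"""Feature extraction for cardiomyocyte functional assays.

Covers the four raw readouts of the functional characterization and one
derived quantity:

* Ca2+ transients -- background-corrected pseudoratio
  ``dF/F = (F - F_base) / (F_base - B)`` and per-transient amplitude,
  10%-to-peak upstroke time and 50%-decay time;
* action potentials -- amplitude, maximum upstroke / most negative decay
  dV/dt, APD50/APD90 (measured from the max-dV/dt instant), MDP and firing
  rate;
* contractile force -- cantilever (``F = k * delta``) or beam-bending
  (``F = 3 E I / L^3 * delta``) conversion of deflection traces and twitch
  force per contraction;
* conduction velocity -- least-squares plane fit of a per-pixel activation
  time map, speed = 1 / |gradient|;
* qPCR fold change -- ``2 ** (-ddCt)`` relative quantification.

Peak detection is deterministic: threshold = baseline + 4 x the MAD-based
noise estimate, with a configurable minimum inter-peak interval (200 ms by
default).  Features whose defining crossing is never reached (e.g. a decay
truncated before 50%) are reported as missing, never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

MAD_SCALE = 1.4826  # MAD -> sd for Gaussian noise


@dataclass
class Trace:
    """Uniformly sampled time series (fluorescence, voltage or deflection)."""

    values: np.ndarray
    sampling_rate: float  # Hz
    kind: str = "fluorescence"  # fluorescence | voltage | deflection | force
    stim_times: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace must be a 1-d vector with >= 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite trace values")
        if self.stim_times is not None:
            self.stim_times = np.asarray(self.stim_times, dtype=float)
            if np.any(self.stim_times < 0) or np.any(self.stim_times > self.duration):
                raise ValueError("stim_times outside trace duration")

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate


@dataclass
class TransientFeatures:
    """Per-transient Ca2+ features plus their means (missing-aware)."""

    per_transient: pd.DataFrame
    amplitude_mean: float
    upstroke_time_mean: float
    decay50_time_mean: float


@dataclass
class APFeatures:
    """Per-action-potential features plus their means."""

    per_ap: pd.DataFrame
    amplitude_mean: float  # mV
    upstroke_velocity_mean: float  # mV/ms
    decay_velocity_mean: float  # mV/ms
    apd50_mean: float  # ms
    apd90_mean: float  # ms
    mdp_mean: float  # mV
    firing_rate: float  # Hz; NaN when only one AP is present


@dataclass
class ForceModel:
    """Deflection-to-force conversion: calibrated cantilever or end-loaded beam."""

    mode: str  # cantilever | beam
    k: float | None = None  # uN/um (cantilever spring constant)
    E: float | None = None  # elastic modulus
    I: float | None = None  # second moment of area
    L: float | None = None  # beam length

    def __post_init__(self) -> None:
        if self.mode == "cantilever":
            if self.k is None or self.k <= 0:
                raise ValueError("cantilever mode needs spring constant k > 0")
        elif self.mode == "beam":
            if any(v is None or v <= 0 for v in (self.E, self.I, self.L)):
                raise ValueError("beam mode needs E, I, L > 0")
        else:
            raise ValueError(f"unknown force model mode {self.mode!r}")

    @property
    def stiffness(self) -> float:
        """Force per unit tip deflection."""
        if self.mode == "cantilever":
            return float(self.k)
        return 3.0 * self.E * self.I / self.L**3


@dataclass
class ActivationMap:
    """Grid of per-pixel activation times (ms); non-activated pixels are NaN."""

    times: np.ndarray
    pixel_pitch: float  # mm per pixel
    origin: tuple[float, float] = (0.0, 0.0)  # (row, col) of the stimulus

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 2:
            raise ValueError("activation map must be 2-d")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    def subgrid(self, rows: slice, cols: slice) -> "ActivationMap":
        """Restrict the map to a rectangular sector (origin preserved)."""
        r0 = rows.indices(self.times.shape[0])[0]
        c0 = cols.indices(self.times.shape[1])[0]
        return ActivationMap(
            self.times[rows, cols],
            self.pixel_pitch,
            (self.origin[0] - r0, self.origin[1] - c0),
        )


# -- Ca2+ transients -------------------------------------------------------


def pseudoratio(t: Trace, baseline_window: tuple[float, float], background: float) -> Trace:
    """Background-corrected ``dF/F = (F - F_base) / (F_base - B)``.

    ``F_base`` is the mean fluorescence over ``baseline_window`` (seconds);
    it must exceed the background ``B``.
    """
    lo, hi = baseline_window
    if not 0 <= lo < hi <= t.duration + 1e-12:
        raise ValueError("baseline window must lie inside the trace")
    i0 = int(round(lo * t.sampling_rate))
    i1 = max(i0 + 1, int(round(hi * t.sampling_rate)))
    f_base = t.values[i0:i1].mean()
    if f_base <= background:
        raise ValueError(f"F_base={f_base:.3g} must exceed background B={background:.3g}")
    dff = (t.values - f_base) / (f_base - background)
    return Trace(dff, t.sampling_rate, kind="fluorescence", stim_times=t.stim_times)


def noise_sd(values: np.ndarray) -> float:
    """Robust sample-noise estimate from the first difference.

    ``1.4826 * median(|dv|) / sqrt(2)`` is insensitive to the slow signal
    component, unlike a MAD of the raw trace which event-rich recordings
    contaminate.
    """
    dv = np.abs(np.diff(np.asarray(values, dtype=float)))
    return MAD_SCALE * float(np.median(dv)) / np.sqrt(2.0)


def smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; ``window <= 1`` is the identity."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    kernel = np.ones(window) / window
    padded = np.pad(np.asarray(values, dtype=float), window, mode="edge")
    return np.convolve(padded, kernel, mode="same")[window:-window]


def detect_peaks(
    t: Trace,
    min_interval: float = 0.2,
    threshold: float | None = None,
    min_prominence: float | None = None,
) -> np.ndarray:
    """Deterministic event-peak detection.

    Peaks must exceed ``baseline + 4 x noise`` (median baseline, robust
    derivative-based noise estimate), be at least ``min_interval`` seconds
    apart, and have prominence of at least half the trace's peak-to-baseline
    range (so noise maxima riding on a slope are never counted as events).
    The defaults presume events of comparable amplitude; both thresholds can
    be overridden.
    """
    v = t.values
    baseline = float(np.median(v))
    noise = noise_sd(v)
    if threshold is None:
        threshold = baseline + 4.0 * noise
    if min_prominence is None:
        min_prominence = max(4.0 * noise, 0.5 * (float(v.max()) - baseline))
    distance = max(1, int(round(min_interval * t.sampling_rate)))
    peaks, _ = sps.find_peaks(
        v, height=threshold, distance=distance, prominence=min_prominence
    )
    return peaks


def _cross_up(v: np.ndarray, start: int, stop: int, level: float) -> float | None:
    """First upward crossing index (fractional) of ``level`` in v[start:stop]."""
    for i in range(start + 1, stop + 1):
        if v[i] >= level and v[i - 1] < level:
            return i - 1 + (level - v[i - 1]) / (v[i] - v[i - 1])
    return None


def _cross_down(v: np.ndarray, start: int, stop: int, level: float) -> float | None:
    """First downward crossing index (fractional) of ``level`` in v[start:stop]."""
    for i in range(start + 1, stop):
        if v[i] <= level and v[i - 1] > level:
            return i - 1 + (v[i - 1] - level) / (v[i - 1] - v[i])
    return None


def calcium_features(
    dff: Trace,
    stim_times: np.ndarray | None = None,
    min_interval: float = 0.2,
    smooth_window: int = 15,
    threshold: float | None = None,
    min_prominence: float | None = None,
) -> TransientFeatures:
    """Amplitude, 10%-to-peak upstroke time and 50%-decay time per transient.

    The pre-transient baseline of each transient is the minimum of the trace
    between the previous peak (or trace start) and the peak.  The upstroke
    time runs from the interpolated 10%-of-amplitude crossing on the rising
    limb to the peak sample; the 50%-decay time runs from the peak to the
    interpolated half-amplitude crossing and is flagged missing when the
    decay is truncated.  Extraction runs on a lightly smoothed copy of the
    trace (centered moving average, ``smooth_window`` samples) so extremum
    estimates are not biased upward by sample noise; ``smooth_window=1``
    disables this.
    """
    v = smooth(dff.values, smooth_window)
    rate = dff.sampling_rate
    peaks = detect_peaks(
        Trace(v, rate, kind=dff.kind),
        min_interval=min_interval,
        threshold=threshold,
        min_prominence=min_prominence,
    )
    if peaks.size == 0:
        raise ValueError("no detectable transient")
    rows = []
    for n, pk in enumerate(peaks):
        seg_start = peaks[n - 1] if n > 0 else 0
        base_idx = seg_start + int(np.argmin(v[seg_start : pk + 1]))
        base = v[base_idx]
        amp = v[pk] - base
        level10 = base + 0.1 * amp
        c10 = _cross_up(v, base_idx, pk, level10)
        upstroke = (pk - c10) / rate if c10 is not None else np.nan
        seg_end = peaks[n + 1] if n + 1 < peaks.size else v.size
        level50 = v[pk] - 0.5 * amp
        c50 = _cross_down(v, pk, seg_end, level50)
        rows.append(
            {
                "peak_time": pk / rate,
                "amplitude": amp,
                "upstroke_time": upstroke,
                "decay50_time": (c50 - pk) / rate if c50 is not None else np.nan,
                "decay50_missing": c50 is None,
            }
        )
    per = pd.DataFrame(rows)
    return TransientFeatures(
        per,
        float(per["amplitude"].mean()),
        float(np.nanmean(per["upstroke_time"])),
        float(np.nanmean(per["decay50_time"])) if not per["decay50_time"].isna().all() else np.nan,
    )


# -- action potentials -----------------------------------------------------


def ap_features(
    v: Trace,
    stim_times: np.ndarray | None = None,
    threshold: float | None = None,
    min_interval: float = 0.2,
    smooth_window: int = 5,
) -> APFeatures:
    """Per-AP amplitude, dV/dt extrema, APD50/APD90, MDP and firing rate.

    APDx is measured from the instant of maximum upstroke dV/dt to the
    interpolated repolarization crossing of ``peak - x% * amplitude``.
    dV/dt uses the centered difference and is reported in mV/ms.  Extraction
    runs on a lightly smoothed copy of the trace (``smooth_window`` samples,
    1 disables).
    """
    y = smooth(v.values, smooth_window)
    rate = v.sampling_rate
    peaks = detect_peaks(
        Trace(y, rate, kind=v.kind), min_interval=min_interval, threshold=threshold
    )
    if peaks.size == 0:
        raise ValueError("no action potential detected")
    dvdt = np.gradient(y) * rate / 1000.0  # mV/ms
    rows = []
    for n, pk in enumerate(peaks):
        prev = peaks[n - 1] if n > 0 else 0
        dia = y[prev : pk + 1]
        mdp_idx = prev + int(np.argmin(dia))
        mdp = y[mdp_idx]
        amp = y[pk] - mdp
        rise = slice(mdp_idx, pk + 1)
        up_rel = int(np.argmax(dvdt[rise]))
        up_idx = mdp_idx + up_rel
        upstroke_velocity = dvdt[up_idx]
        nxt = peaks[n + 1] if n + 1 < peaks.size else y.size
        decay_velocity = float(dvdt[pk:nxt].min()) if nxt > pk else np.nan
        apd = {}
        for frac, name in ((0.5, "apd50"), (0.9, "apd90")):
            level = y[pk] - frac * amp
            cross = _cross_down(y, pk, nxt, level)
            apd[name] = (cross - up_idx) / rate * 1000.0 if cross is not None else np.nan
        rows.append(
            {
                "peak_time": pk / rate,
                "amplitude": amp,
                "upstroke_velocity": float(upstroke_velocity),
                "decay_velocity": decay_velocity,
                "apd50": apd["apd50"],
                "apd90": apd["apd90"],
                "mdp": mdp,
            }
        )
    per = pd.DataFrame(rows)
    if peaks.size >= 2:
        firing = (peaks.size - 1) / ((peaks[-1] - peaks[0]) / rate)
    else:
        firing = np.nan  # undefined for a single AP
    return APFeatures(
        per,
        float(per["amplitude"].mean()),
        float(per["upstroke_velocity"].mean()),
        float(np.nanmean(per["decay_velocity"])),
        float(np.nanmean(per["apd50"])),
        float(np.nanmean(per["apd90"])),
        float(per["mdp"].mean()),
        float(firing),
    )


# -- force -----------------------------------------------------------------


def force_from_deflection(d: Trace, model: ForceModel) -> Trace:
    """Convert a deflection trace to force, ``F = stiffness * delta``."""
    return Trace(
        d.values * model.stiffness, d.sampling_rate, kind="force", stim_times=d.stim_times
    )


def twitch_forces(f: Trace, min_interval: float = 0.2) -> pd.DataFrame:
    """Twitch force per contraction: peak minus the preceding diastolic minimum."""
    peaks = detect_peaks(f, min_interval=min_interval)
    if peaks.size == 0:
        raise ValueError("no contraction detected")
    rows = []
    for n, pk in enumerate(peaks):
        prev = peaks[n - 1] if n > 0 else 0
        baseline = f.values[prev : pk + 1].min()
        rows.append(
            {"peak_time": pk / f.sampling_rate, "twitch_force": f.values[pk] - baseline}
        )
    return pd.DataFrame(rows)


# -- conduction velocity ---------------------------------------------------


def conduction_velocity(amap: ActivationMap) -> tuple[float, np.ndarray]:
    """Propagation speed (mm/s) and direction from a plane fit of the map.

    Fits ``t(x, y) = t0 + gx * x + gy * y`` by least squares over activated
    pixels (coordinates in mm via the pixel pitch, times in ms); the speed is
    ``1 / |(gx, gy)|`` converted to mm/s and the direction is the unit
    gradient (pointing away from the stimulus).
    """
    rows, cols = np.nonzero(np.isfinite(amap.times))
    t = amap.times[rows, cols]
    if t.size < 10:
        raise ValueError("need at least 10 activated pixels")
    if np.ptp(t) == 0:
        raise ValueError("uniform activation times: degenerate fit")
    x = cols * amap.pixel_pitch
    y = rows * amap.pixel_pitch
    design = np.column_stack([np.ones_like(x), x, y])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("collinear activated pixels: rank-deficient fit")
    coef, *_ = np.linalg.lstsq(design, t, rcond=None)
    grad = coef[1:]  # ms per mm
    gnorm = np.linalg.norm(grad)
    if gnorm < 1e-12:
        raise ValueError("zero activation-time gradient: degenerate fit")
    speed_mm_s = 1000.0 / gnorm
    return float(speed_mm_s), grad / gnorm


# -- qPCR ------------------------------------------------------------------


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression ``2 ** (-ddCt)`` normalized to a reference gene.

    ``ddCt = (Ct_target,sample - Ct_ref,sample) -
    (Ct_target,control - Ct_ref,control)``; assay efficiency is assumed to be
    2 (one doubling per cycle).
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("missing Ct value")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
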