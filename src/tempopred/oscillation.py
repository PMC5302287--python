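"""Oscillatory analyses: delta-band phase, ITPC, optimal phase, Morlet TFR.

Phase convention throughout: 0 radians = the peak of the cosine, so a
signal ``cos(2*pi*f*t)`` has phase 0 at its peaks.  Delta phase is the
analytic-signal (Hilbert) angle of the 0.5-3 Hz filtered continuous data,
computed per electrode and then averaged circularly (angle of the mean
unit phasor) across the occipital cluster.

ITPC (inter-trial phase coherence) is the resultant length of per-trial
unit phasors at a fixed lock time: 1 for perfect alignment, 0 for a
uniform phase distribution; for von Mises distributed phases with
concentration kappa its large-n expectation is I1(kappa)/I0(kappa).

The time-frequency transform is a complex Morlet wavelet family with a
frequency-domain ratio of 8 (sigma_f = f/8, sigma_t = 1/(2*pi*sigma_f)),
normalised to unit passband gain: a unit-amplitude sinusoid at the centre
frequency yields amplitude 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, hilbert

__all__ = [
    "PhaseSet",
    "TFR",
    "circ_mean",
    "delta_phase",
    "itpc",
    "optimal_phase",
    "phase_rt_curve",
    "morlet_tfr",
    "alpha_window_stat",
]

ALPHA_BAND_HZ = (8.0, 13.0)
ALPHA_WINDOW_MS = (700.0, 900.0)
ALPHA_BASELINE_MS = (0.0, 100.0)


def wrap_angle(phi):
    return np.pi - np.mod(np.pi - np.asarray(phi), 2 * np.pi)


def circ_mean(angles: np.ndarray, axis=None) -> np.ndarray | float:
    """Circular mean direction (angle of the mean unit phasor)."""
    return np.angle(np.exp(1j * np.asarray(angles)).mean(axis=axis))


@dataclass
class PhaseSet:
    """Per-trial phase angles at a lock time (radians, in (-pi, pi])."""

    angles: np.ndarray
    lock: str = "target"
    condition: str | None = None
    cue_soa: int | None = None

    def __post_init__(self) -> None:
        self.angles = wrap_angle(np.asarray(self.angles, dtype=float))

    @property
    def itpc(self) -> float:
        return itpc(self.angles)

    @property
    def mean_angle(self) -> float:
        return float(circ_mean(self.angles))


@dataclass
class TFR:
    """Trial-resolved time-frequency amplitude, (n_trials, n_freqs, n_times)."""

    amplitude: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    ratio: float = 8.0


def delta_phase(continuous_filtered: np.ndarray, electrodes: list[int] | None = None) -> np.ndarray:
    """Instantaneous phase of delta-filtered data, circularly averaged over electrodes.

    Input must already be band-passed (0.5-3 Hz) and unsegmented.  Per
    electrode the Hilbert analytic phase is taken; electrodes are combined
    as the angle of the mean unit phasor, which respects circularity.
    Samples where the across-electrode resultant vanishes get NaN.
    """
    x = np.atleast_2d(np.asarray(continuous_filtered, dtype=float))
    if electrodes is not None:
        x = x[electrodes]
    phasors = np.exp(1j * np.angle(hilbert(x, axis=-1)))
    mean_phasor = phasors.mean(axis=0)
    phase = np.angle(mean_phasor)
    phase[np.abs(mean_phasor) < 1e-12] = np.nan
    return phase


def itpc(angles: np.ndarray) -> float:
    """Resultant length of unit phasors across trials (in [0, 1])."""
    a = np.asarray(angles, dtype=float)
    if a.size < 2:
        raise ValueError("ITPC needs at least 2 trials")
    return float(np.abs(np.exp(1j * a).mean()))


def optimal_phase(angles: np.ndarray, rts: np.ndarray, fraction: float = 1 / 3) -> float:
    """Circular mean phase of the fastest ``fraction`` of trials.

    This estimates the subject's optimal phase for performance from the
    Random condition; it is invariant to adding a constant to all RTs.
    Raises if fewer than 3 trials qualify.
    """
    a = np.asarray(angles, dtype=float)
    r = np.asarray(rts, dtype=float)
    if a.shape != r.shape:
        raise ValueError("angles and rts must align")
    k = int(np.floor(fraction * a.size))
    if k < 3:
        raise ValueError("fewer than 3 qualifying trials for optimal-phase estimate")
    fastest = np.argsort(r, kind="stable")[:k]
    return float(circ_mean(a[fastest]))


def phase_rt_curve(
    phases_per_subject: list[np.ndarray],
    rts_per_subject: list[np.ndarray],
    optimal_per_subject: np.ndarray,
    window_rad: float = np.pi / 2,
    n_points: int = 64,
) -> pd.DataFrame:
    """Standardised RT as a function of circular distance from the optimal phase.

    RTs are z-scored within subject; phases are re-centred so each
    subject's optimal phase is 0; pooled points are smoothed with a moving
    circular window of width pi/2.  Returns a DataFrame with columns
    ``distance`` (grid over (-pi, pi]) and ``rt_z``.
    """
    dist, rtz = [], []
    for ph, rt, opt in zip(phases_per_subject, rts_per_subject, optimal_per_subject):
        rt = np.asarray(rt, dtype=float)
        sd = rt.std(ddof=1)
        z = (rt - rt.mean()) / (sd if sd > 0 else 1.0)
        dist.append(wrap_angle(np.asarray(ph) - opt))
        rtz.append(z)
    dist = np.concatenate(dist)
    rtz = np.concatenate(rtz)
    grid = np.linspace(-np.pi, np.pi, n_points, endpoint=False)
    curve = np.full(n_points, np.nan)
    for i, g in enumerate(grid):
        d = np.abs(wrap_angle(dist - g))
        sel = d <= window_rad / 2
        if sel.any():
            curve[i] = rtz[sel].mean()
    return pd.DataFrame({"distance": grid, "rt_z": curve})


def _morlet_kernel(freq: float, fs: float, ratio: float) -> np.ndarray:
    sigma_f = freq / ratio
    sigma_t = 1.0 / (2 * np.pi * sigma_f)
    half = int(np.ceil(5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(-(t**2) / (2 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    # unit passband gain: |conv| = A for A*cos(2*pi*f*t)
    kernel /= 0.5 * np.abs(np.exp(-(t**2) / (2 * sigma_t**2))).sum()
    return kernel


def morlet_tfr(
    epochs: np.ndarray,
    fs: float,
    times_ms: np.ndarray,
    freqs: np.ndarray | None = None,
    ratio: float = 8.0,
    pad_ms: float = 1000.0,
) -> TFR:
    """Complex Morlet amplitude transform (1-30 Hz, 1 Hz steps, ratio 8).

    ``epochs`` is (n_trials, n_times) -- channel averaging is done by the
    caller.  Epochs must extend at least ``pad_ms`` beyond the analysis
    range on both sides; those edges absorb wavelet edge artifacts and are
    discarded from the returned TFR.
    """
    freqs = np.arange(1.0, 31.0) if freqs is None else np.asarray(freqs, dtype=float)
    x = np.atleast_2d(np.asarray(epochs, dtype=float))
    times_ms = np.asarray(times_ms, dtype=float)
    n_pad = int(round(pad_ms * fs / 1000.0))
    if x.shape[1] != times_ms.size:
        raise ValueError("epochs and times grid mismatch")
    if x.shape[1] <= 2 * n_pad:
        raise ValueError("epoch too short for the requested edge padding")
    amp = np.empty((x.shape[0], freqs.size, x.shape[1] - 2 * n_pad))
    for fi, f in enumerate(freqs):
        kern = _morlet_kernel(f, fs, ratio)
        conv = fftconvolve(x, kern[None, :], mode="same", axes=1)
        amp[:, fi] = np.abs(conv[:, n_pad:-n_pad])
    return TFR(amplitude=amp, freqs=freqs, times_ms=times_ms[n_pad:-n_pad], ratio=ratio)


def alpha_window_stat(
    tfr: TFR,
    band_hz: tuple[float, float] = ALPHA_BAND_HZ,
    window_ms: tuple[float, float] = ALPHA_WINDOW_MS,
    baseline_ms: tuple[float, float] = ALPHA_BASELINE_MS,
    mode: str = "subtract",
) -> float:
    """Mean alpha-band amplitude in the 700-900 ms post-WS window.

    The TFR times must be WS-locked.  Baseline (0-100 ms post-WS) is
    subtracted from (or, in ratio mode, divides) the band amplitude before
    averaging over the window; ratio mode yields a unitless relative change.
    """
    fmask = (tfr.freqs >= band_hz[0]) & (tfr.freqs <= band_hz[1])
    wmask = (tfr.times_ms >= window_ms[0]) & (tfr.times_ms < window_ms[1])
    bmask = (tfr.times_ms >= baseline_ms[0]) & (tfr.times_ms < baseline_ms[1])
    if not (fmask.any() and wmask.any() and bmask.any()):
        raise ValueError("band / window / baseline outside the TFR grid")
    band = tfr.amplitude[:, fmask].mean(axis=1)  # (trials, times)
    base = band[:, bmask].mean(axis=1, keepdims=True)
    if mode == "subtract":
        corrected = band - base
    elif mode == "ratio":
        corrected = band / base
    else:
        raise ValueError("mode must be 'subtract' or 'ratio'")
    return float(corrected[:, wmask].mean())
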