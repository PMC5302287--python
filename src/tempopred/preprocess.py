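"""EEG preprocessing: filtering, referencing, epoching, artifact and RT cleaning.

Filters are zero-phase Butterworth filters applied forward-backward
(``sosfiltfilt``); the nominal "24 dB/octave" roll-off is realised as a
4th-order design per pass.  The delta filter (0.5-3 Hz) is applied to the
unsegmented continuous data, before epoching, so that epoch edges do not
distort the phase estimate.  Artifact rejection flags epochs with absolute
activity above 100 uV or a peak-to-peak change above 100 uV within any
sliding 200 ms window on any channel.  RT cleaning removes responses
shorter than 50 ms and responses more than 3 SD from the mean of their
condition x validity cell (single pass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d

__all__ = [
    "EpochSet",
    "highpass",
    "bandpass_delta",
    "rereference",
    "segment_and_baseline",
    "reject_artifacts",
    "clean_rts",
]

ARTIFACT_ABS_UV = 100.0
ARTIFACT_STEP_UV = 100.0
ARTIFACT_STEP_WINDOW_MS = 200.0
RT_FLOOR_MS = 50.0
RT_SD_CUTOFF = 3.0


@dataclass
class EpochSet:
    """Cut epochs plus their retention mask.

    ``data`` has shape (n_trials, n_channels, n_times); ``times_ms`` is
    relative to the lock event.  ``mask`` marks epochs retained after
    artifact rejection; data itself is never modified by rejection.
    """

    data: np.ndarray
    times_ms: np.ndarray
    fs: float
    ch_names: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    events: pd.DataFrame | None = None
    baseline_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.data.shape[0], dtype=bool)
        if len(self.mask) != self.data.shape[0]:
            raise ValueError("mask length must equal trial count")

    @property
    def retained(self) -> np.ndarray:
        return self.data[self.mask]

    def average(self, picks: list[int] | None = None) -> np.ndarray:
        """Trial average, optionally over a channel subset, -> (n_times,)."""
        d = self.retained
        if picks is not None:
            d = d[:, picks]
        return d.mean(axis=(0, 1))


def _butter_filtfilt(data: np.ndarray, fs: float, btype: str, cutoff, order: int = 4) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    sos = signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def highpass(continuous: np.ndarray, fs: float, cutoff_hz: float = 0.1, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass (default 0.1 Hz, 24 dB/octave)."""
    return _butter_filtfilt(continuous, fs, "highpass", cutoff_hz, order)


def bandpass_delta(
    continuous: np.ndarray, fs: float, band_hz: tuple[float, float] = (0.5, 3.0), order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass for delta (0.5-3 Hz), on unsegmented data."""
    return _butter_filtfilt(continuous, fs, "bandpass", list(band_hz), order)


def rereference(
    continuous: np.ndarray, ch_names: list[str], reference: list[str] | str = ("M1", "M2")
) -> np.ndarray:
    """Subtract the mean of the reference channel(s) from every channel.

    ``reference=("M1","M2")`` implements the linked-mastoid scheme used for
    ERP analysis; a single channel (e.g. nose) is supported for the
    recording-stage scheme.  Idempotent: referencing twice equals once.
    """
    if isinstance(reference, str):
        reference = [reference]
    try:
        idx = [ch_names.index(ch) for ch in reference]
    except ValueError as exc:
        raise ValueError(f"reference channel missing from {ch_names}") from exc
    ref = np.asarray(continuous)[..., idx, :].mean(axis=-2, keepdims=True)
    return np.asarray(continuous) - ref


def segment_and_baseline(
    continuous: np.ndarray,
    fs: float,
    event_samples: np.ndarray,
    window_ms: tuple[float, float],
    baseline_ms: tuple[float, float] | None = None,
    ch_names: list[str] | None = None,
    events: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut epochs around event samples and subtract the baseline mean.

    Epochs exceeding the recording bounds are dropped with a warning (their
    event rows are dropped from ``events`` too).  ``baseline_ms`` must lie
    inside the epoch window; pass None to skip correction (e.g. for
    phase data, where subtraction is meaningless).
    """
    x = np.atleast_2d(np.asarray(continuous))
    n_samples = x.shape[-1]
    start = int(round(window_ms[0] * fs / 1000.0))
    stop = int(round(window_ms[1] * fs / 1000.0))
    times = np.arange(start, stop) * 1000.0 / fs
    if baseline_ms is not None and not (
        window_ms[0] <= baseline_ms[0] and baseline_ms[1] <= window_ms[1]
    ):
        raise ValueError("baseline window must lie inside the epoch window")

    event_samples = np.asarray(event_samples, dtype=int)
    ok = (event_samples + start >= 0) & (event_samples + stop <= n_samples)
    if not ok.all():
        warnings.warn(f"dropped {np.sum(~ok)} epoch(s) exceeding record bounds")
    kept = event_samples[ok]
    data = np.stack([x[:, s + start : s + stop] for s in kept]) if kept.size else np.empty(
        (0, x.shape[0], stop - start)
    )
    if baseline_ms is not None and kept.size:
        bmask = (times >= baseline_ms[0]) & (times < baseline_ms[1])
        data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    if events is not None:
        events = events.iloc[np.flatnonzero(ok)].reset_index(drop=True)
    return EpochSet(
        data=data, times_ms=times, fs=fs,
        ch_names=ch_names or [f"ch{i}" for i in range(x.shape[0])],
        events=events, baseline_ms=baseline_ms,
    )


def reject_artifacts(
    epochs: EpochSet,
    abs_uv: float = ARTIFACT_ABS_UV,
    step_uv: float = ARTIFACT_STEP_UV,
    step_window_ms: float = ARTIFACT_STEP_WINDOW_MS,
) -> EpochSet:
    """Flag epochs with |amplitude| > 100 uV or >100 uV change in 200 ms.

    The change criterion is max - min within every sliding 200 ms window
    (stride one sample).  Returns a new EpochSet sharing data with an
    updated mask.
    """
    data = epochs.data
    win = max(int(round(step_window_ms * epochs.fs / 1000.0)), 2)
    bad_abs = np.abs(data).max(axis=(1, 2)) > abs_uv
    ptp = maximum_filter1d(data, win, axis=2, mode="nearest") - minimum_filter1d(
        data, win, axis=2, mode="nearest"
    )
    bad_step = ptp.max(axis=(1, 2)) > step_uv
    mask = epochs.mask & ~(bad_abs | bad_step)
    return EpochSet(
        data=epochs.data, times_ms=epochs.times_ms, fs=epochs.fs,
        ch_names=epochs.ch_names, mask=mask, events=epochs.events,
        baseline_ms=epochs.baseline_ms,
    )


def clean_rts(
    rt_table: pd.DataFrame,
    rt_col: str = "rt_ms",
    group_cols: tuple[str, ...] = ("condition", "validity"),
    floor_ms: float = RT_FLOOR_MS,
    sd_cutoff: float = RT_SD_CUTOFF,
) -> pd.DataFrame:
    """Drop RTs below 50 ms or beyond 3 SD of their condition x validity cell.

    The SD rule is a single pass per group (per subject if a ``subject``
    column is present); groups with fewer than 3 responses skip the SD rule
    with a warning.
    """
    df = rt_table.dropna(subset=[rt_col]).copy()
    groups = list(group_cols)
    if "subject" in df.columns and "subject" not in groups:
        groups = ["subject"] + groups
    df = df[df[rt_col] >= floor_ms]

    def _sd_rule(g: pd.DataFrame) -> pd.DataFrame:
        if len(g) < 3:
            warnings.warn("group with < 3 trials: SD rule skipped")
            return g
        mu, sd = g[rt_col].mean(), g[rt_col].std(ddof=1)
        if sd == 0:
            return g
        return g[(g[rt_col] - mu).abs() <= sd_cutoff * sd]

    out = df.groupby(groups, group_keys=False, observed=True)[df.columns].apply(_sd_rule)
    return out.reset_index(drop=True)
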