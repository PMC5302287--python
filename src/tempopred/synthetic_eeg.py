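"""Synthetic EEG and reaction-time generator with known ground truth.

Every effect the analysis pipeline measures is planted with a controllable
magnitude so downstream stages can be validated by parameter recovery:

* central channels carry the piecewise CNV waveform (via
  :func:`tempopred.erp.cnv_model_predict`) peaking at the expected target
  time, with a condition-specific delay before resolution;
* occipital channels carry a 10 Hz alpha oscillation whose envelope dips by
  a fractional depth around the expected target time, and a 1.5 Hz delta
  component whose Hilbert phase at target time is drawn von Mises around a
  subject-specific optimal angle (the delta component is constructed
  backward from the target -- a generator convenience, not a mechanistic
  claim);
* parietal channels carry a post-target P3 bump whose latency shifts with
  cue validity;
* RTs couple to the drawn delta phase (cosine tuning around the optimal
  angle) plus a validity penalty and Gaussian noise, floored at 50 ms;
* all channels receive 1/f-shaped plus white noise.

Defaults put the CNV peak (-5 uV) against 10 uV total noise SD at 256 Hz --
realistic single-trial SNR while keeping recovery feasible at session trial
counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import stimgen
from .erp import CNVParams, cnv_model_predict
from .stimgen import Condition, TrialSpec, Validity

__all__ = [
    "GroundTruth",
    "SyntheticRecording",
    "CHANNELS",
    "CENTRAL_CLUSTER",
    "OCCIPITAL_CLUSTER",
    "PARIETAL_CLUSTER",
    "synth_epoch",
    "synth_rt",
    "assemble_recording",
    "write_recording",
    "read_raw_edf",
]

CENTRAL_CLUSTER = ["FC1", "FCz", "FC2", "C1", "Cz", "C2", "CP1", "CPz", "CP2"]
OCCIPITAL_CLUSTER = ["PO3", "PO4", "PO7", "PO8", "O1", "O2"]
PARIETAL_CLUSTER = ["Pz", "P1", "P2"]
REFERENCE_CHANNELS = ["M1", "M2"]
CHANNELS = CENTRAL_CLUSTER + OCCIPITAL_CLUSTER + PARIETAL_CLUSTER + REFERENCE_CHANNELS


@dataclass
class GroundTruth:
    """Generator parameter bundle; the acceptance surface for recovery tests."""

    fs: float = 256.0
    n_subjects: int = 1

    # CNV (central cluster), times ms post-WS, amplitudes uV
    cnv_peak_uv: float = -5.0
    cnv_t0_ms: float = 200.0
    #: delay between buildup termination and resolution initiation (T2 - T1)
    cnv_resolution_gap_ms: dict = field(
        default_factory=lambda: {"Rhythmic": 0.0, "RepeatedInterval": 400.0, "Random": 0.0}
    )
    #: resolution slope; chosen so the planted waveform stays within the
    #: piecewise model family over the whole 0-1400 ms analysis window
    #: (it reaches baseline only at ~1400 ms for an immediate resolution)
    cnv_s2_uv_ms: float = 0.007

    # occipital alpha
    alpha_freq_hz: float = 10.0
    alpha_amp_uv: float = 4.0
    alpha_mod_depth: float = 0.3
    alpha_dip_sigma_ms: float = 150.0

    # occipital delta
    delta_freq_hz: float = 1.5
    delta_amp_uv: float = 5.0
    delta_sigma_ms: float = 600.0
    delta_kappa: dict = field(
        default_factory=lambda: {"Rhythmic": 2.0, "RepeatedInterval": 2.0, "Random": 0.3}
    )
    #: per-subject optimal phase angles (radians); filled at construction
    optimal_angles: np.ndarray | None = None

    # parietal P3
    p3_amp_uv: float = 8.0
    p3_latency_ms: float = 350.0
    p3_validity_shift_ms: float = 40.0
    p3_sigma_ms: float = 70.0

    # behaviour (ms)
    rt_base_ms: dict = field(
        default_factory=lambda: {"Rhythmic": 330.0, "RepeatedInterval": 330.0, "Random": 365.0}
    )
    rt_validity_penalty_ms: dict = field(
        default_factory=lambda: {"Rhythmic": 45.0, "RepeatedInterval": 25.0, "Random": 10.0}
    )
    rt_phase_coupling_ms: float = 20.0
    rt_noise_sd_ms: float = 50.0

    # noise
    noise_white_sd_uv: float = 5.0
    noise_pink_sd_uv: float = 8.0
    noise_exponent: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.alpha_mod_depth < 1):
            raise ValueError("alpha_mod_depth must be in [0, 1)")
        if any(k < 0 for k in self.delta_kappa.values()):
            raise ValueError("delta_kappa must be >= 0")
        if self.fs <= 60:
            raise ValueError("sampling rate must exceed twice the 30 Hz analysis ceiling")
        if self.optimal_angles is None:
            # fixed spread of subject optimal angles (reproducible default)
            self.optimal_angles = np.linspace(-np.pi / 2, np.pi / 2, self.n_subjects)
        self.optimal_angles = np.atleast_1d(np.asarray(self.optimal_angles, dtype=float))
        self.n_subjects = len(self.optimal_angles)

    def cnv_params(self, condition: str, cue_soa: int) -> CNVParams:
        """Piecewise CNV parameters for one (condition, expected SOA) context."""
        cond = Condition(condition).value
        if cond == "Random":
            t0, t1 = self.cnv_t0_ms, 1000.0
            peak = 0.6 * self.cnv_peak_uv
        else:
            t0, t1 = self.cnv_t0_ms, float(cue_soa)
            peak = self.cnv_peak_uv
        t2 = t1 + self.cnv_resolution_gap_ms[cond]
        return CNVParams(
            t0=t0, s1=peak / (t1 - t0), t1=t1, t2=t2, s2=self.cnv_s2_uv_ms
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["optimal_angles"] = list(map(float, self.optimal_angles))
        return json.dumps(d, indent=2)


@dataclass
class SyntheticRecording:
    """Continuous multichannel recording plus its event/RT table and truth."""

    data: np.ndarray  # (n_channels, n_samples), uV
    fs: float
    ch_names: list[str]
    events: pd.DataFrame
    ground_truth: GroundTruth
    subject: int = 0

    def __post_init__(self) -> None:
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if (self.events["onset_ms"].max() / 1000.0) * self.fs > self.data.shape[1]:
            raise ValueError("event onsets outside recording bounds")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def picks(self, names: list[str]) -> list[int]:
        return [self.ch_names.index(n) for n in names]


def one_over_f_noise(
    n: int, fs: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD noise with a 1/f**exponent power spectrum (spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _gauss(t_ms: np.ndarray, center_ms: float, sigma_ms: float) -> np.ndarray:
    return np.exp(-((t_ms - center_ms) ** 2) / (2 * sigma_ms**2))


def synth_epoch(
    trial: TrialSpec,
    gt: GroundTruth,
    rng: np.random.Generator,
    subject: int = 0,
) -> tuple[np.ndarray, float]:
    """Synthesize one trial epoch; returns (samples (n_ch, n_t), drawn delta phase).

    The epoch spans trial time 0 .. trial.end_ms.  The delta phase at (the
    possibly expected) target time is drawn von Mises around the subject's
    optimal angle with the condition's concentration.
    """
    fs = gt.fs
    n_t = int(round(trial.end_ms * fs / 1000.0)) + 1
    t_ms = np.arange(n_t) * 1000.0 / fs
    data = np.zeros((len(CHANNELS), n_t))
    cond = trial.condition.value
    ws = trial.ws_time
    expected_target = ws + trial.cue_soa
    target = trial.target_time

    # CNV on the central cluster, clipped at baseline after full resolution
    params = gt.cnv_params(cond, trial.cue_soa)
    rel = t_ms - ws
    cnv = cnv_model_predict(params, np.clip(rel, 0.0, None))
    cnv[rel < 0] = 0.0
    if gt.cnv_peak_uv < 0:
        cnv = np.minimum(cnv, 0.0)
    else:
        cnv = np.maximum(cnv, 0.0)
    for name in CENTRAL_CLUSTER:
        data[CHANNELS.index(name)] += cnv

    # occipital alpha with an anticipatory envelope dip at the expected time
    envelope = gt.alpha_amp_uv * (
        1.0 - gt.alpha_mod_depth * _gauss(t_ms, expected_target, gt.alpha_dip_sigma_ms)
    )
    alpha_phase = rng.uniform(-np.pi, np.pi)
    alpha = envelope * np.cos(2 * np.pi * gt.alpha_freq_hz * t_ms / 1000.0 + alpha_phase)

    # occipital delta, constructed so its phase at target time equals the draw
    kappa = gt.delta_kappa[cond]
    mu = float(gt.optimal_angles[subject])
    if kappa > 0:
        delta_phase = float(rng.vonmises(mu, kappa))
    else:
        delta_phase = float(rng.uniform(-np.pi, np.pi))
    anchor = target if target is not None else expected_target
    delta = (
        gt.delta_amp_uv
        * _gauss(t_ms, anchor, gt.delta_sigma_ms)
        * np.cos(2 * np.pi * gt.delta_freq_hz * (t_ms - anchor) / 1000.0 + delta_phase)
    )
    for name in OCCIPITAL_CLUSTER:
        data[CHANNELS.index(name)] += alpha + delta

    # parietal P3 after an actual target
    if target is not None:
        lat = gt.p3_latency_ms + (
            gt.p3_validity_shift_ms if trial.validity is Validity.INVALID else 0.0
        )
        p3 = gt.p3_amp_uv * _gauss(t_ms, target + lat, gt.p3_sigma_ms)
        for name in PARIETAL_CLUSTER:
            data[CHANNELS.index(name)] += p3

    # noise everywhere
    for ci in range(len(CHANNELS)):
        if gt.noise_pink_sd_uv > 0:
            data[ci] += gt.noise_pink_sd_uv * one_over_f_noise(n_t, fs, gt.noise_exponent, rng)
        if gt.noise_white_sd_uv > 0:
            data[ci] += gt.noise_white_sd_uv * rng.standard_normal(n_t)
    return data, delta_phase


def synth_rt(
    trial: TrialSpec,
    delta_phase_at_target: float,
    gt: GroundTruth,
    rng: np.random.Generator,
    subject: int = 0,
) -> float | None:
    """Draw a reaction time for a target trial; catch trials return None.

    RT = base(condition) + validity penalty [invalid only]
         - a * cos(phase - optimal angle) + Gaussian noise, floored at 50 ms.
    """
    if trial.target_time is None:
        return None
    cond = trial.condition.value
    rt = gt.rt_base_ms[cond]
    if trial.validity is Validity.INVALID:
        rt += gt.rt_validity_penalty_ms[cond]
    rt -= gt.rt_phase_coupling_ms * np.cos(
        delta_phase_at_target - gt.optimal_angles[subject]
    )
    rt += rng.normal(0.0, gt.rt_noise_sd_ms)
    return float(max(rt, 50.0))


def assemble_recording(
    blocks: list[stimgen.BlockSpec],
    gt: GroundTruth,
    rng: np.random.Generator,
    subject: int = 0,
    fixation_ms: int = stimgen.FIXATION_MS,
    inter_trial_ms: int = 1000,
    edge_pad_ms: int = 2000,
) -> SyntheticRecording:
    """Place trial epochs in a continuous record and build the event table.

    Trials are laid out sequentially (fixation + epoch + inter-trial gap),
    so overlap is impossible by construction; the event table carries the
    stimgen design columns plus absolute onsets, RTs on target rows, and the
    drawn per-trial delta phase for ground-truth comparisons.
    """
    fs = gt.fs
    trials = stimgen.session_trials(blocks)
    block_of = {id(t): bi for bi, b in enumerate(blocks) for t in b.trials}

    epochs, rows = [], []
    cursor_ms = edge_pad_ms
    for ti, trial in enumerate(trials):
        cursor_ms += fixation_ms
        data, dphase = synth_epoch(trial, gt, rng, subject)
        rt = synth_rt(trial, dphase, gt, rng, subject)
        start_sample = int(round(cursor_ms * fs / 1000.0))
        epochs.append((start_sample, data))
        for t, lab in trial.onsets:
            rows.append(dict(
                trial_id=ti,
                block=block_of[id(trial)],
                condition=trial.condition.value,
                cue_soa_ms=trial.cue_soa,
                validity=trial.validity.value,
                n_pre_ws=trial.n_pre_ws,
                onset_label=lab,
                onset_ms=cursor_ms + t,
                rt_ms=rt if lab == "target" else np.nan,
                true_delta_phase=dphase if lab in ("target", "ws") else np.nan,
                subject=subject,
            ))
        cursor_ms += trial.end_ms + inter_trial_ms
    cursor_ms += edge_pad_ms

    n_samples = int(round(cursor_ms * fs / 1000.0)) + 1
    data = np.zeros((len(CHANNELS), n_samples))
    # continuous background noise outside epochs keeps filters well-behaved
    for ci in range(len(CHANNELS)):
        data[ci] = gt.noise_white_sd_uv * 0.2 * rng.standard_normal(n_samples)
    for start, ep in epochs:
        if start + ep.shape[1] > n_samples:
            raise ValueError("trial placement exceeds recording bounds")
        data[:, start : start + ep.shape[1]] += ep

    events = pd.DataFrame(rows)
    return SyntheticRecording(
        data=data, fs=fs, ch_names=list(CHANNELS), events=events,
        ground_truth=gt, subject=subject,
    )


def write_recording(rec: SyntheticRecording, out_dir) -> dict:
    """Write a recording to disk: .npy samples, TSV events, JSON sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"sub-{rec.subject:02d}"
    np.save(out / f"{stem}_eeg.npy", rec.data)
    rec.events.to_csv(out / f"{stem}_events.tsv", sep="\t", index=False)
    (out / f"{stem}_truth.json").write_text(rec.ground_truth.to_json())
    meta = {"fs": rec.fs, "ch_names": rec.ch_names, "subject": rec.subject}
    (out / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))
    return {k: str(out / f"{stem}_{k}") for k in ("eeg.npy", "events.tsv", "truth.json", "meta.json")}


def read_raw_edf(path, picks: list[str] | None = None) -> tuple[np.ndarray, float, list[str]]:
    """Read a continuous EDF recording (returns data in uV, fs, channel names).

    Thin wrapper over mne's EDF reader for real-data input; synthetic
    recordings round-trip through :func:`write_recording` instead.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if picks:
        raw.pick(picks)
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
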