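"""Stimulus-stream generation for the three temporal-prediction conditions.

Trials consist of a preparatory stream of visual stimuli, a warning signal
(WS) and -- except on catch trials -- a target.  Three conditions differ in
the temporal structure of the stream:

* ``Rhythmic`` -- perfectly periodic stream at the cue SOA (700 or 1300 ms);
  the target follows the WS at the cue SOA (valid) or at the other SOA
  (invalid).
* ``RepeatedInterval`` -- black/red stimulus pairs; the within-pair interval
  equals the cue SOA while between-pair intervals are jittered, so the
  stream is aperiodic yet the WS-target interval is fully predictable.
* ``Random`` -- all stream intervals jittered around the cue SOA; the target
  SOA is drawn independently, so the stream carries no predictive
  information.

All times are integer milliseconds with trial start at 0; onset times mark
the first sample of the 100 ms stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STIMULUS_DURATION_MS = 100
FIXATION_MS = 500
CATCH_BLANK_MS = 1500
SHORT_SOA_MS = 700
LONG_SOA_MS = 1300

#: between-pair jitter grids of the Repeated-Interval condition (ms)
REPEATED_JITTER = {
    SHORT_SOA_MS: np.arange(1500, 1901, 50),
    LONG_SOA_MS: np.arange(1900, 2701, 100),
}
#: stream-SOA jitter of the Random condition, added to the cue SOA (ms)
RANDOM_JITTER = np.arange(-200, 201, 50)

N_PRE_WS_CHOICES = (4, 5, 6)


class Condition(str, Enum):
    RHYTHMIC = "Rhythmic"
    REPEATED_INTERVAL = "RepeatedInterval"
    RANDOM = "Random"


class Validity(str, Enum):
    VALID = "valid"
    INVALID = "invalid"
    CATCH = "catch"


PREDICTIVE_PROPORTIONS = {Validity.VALID: 0.75, Validity.INVALID: 0.125, Validity.CATCH: 0.125}
RANDOM_PROPORTIONS = {Validity.VALID: 0.4375, Validity.INVALID: 0.4375, Validity.CATCH: 0.125}


def other_soa(cue_soa: int) -> int:
    if cue_soa == SHORT_SOA_MS:
        return LONG_SOA_MS
    if cue_soa == LONG_SOA_MS:
        return SHORT_SOA_MS
    raise ValueError(f"cue SOA must be {SHORT_SOA_MS} or {LONG_SOA_MS} ms, got {cue_soa}")


@dataclass
class TrialSpec:
    """One trial's onset schedule and design labels."""

    condition: Condition
    cue_soa: int
    validity: Validity
    n_pre_ws: int
    #: ordered (time ms, label) with label in {stream_black, stream_red, ws, target}
    onsets: list[tuple[int, str]]
    rng_seed: int = 0
    end_ms: int = 0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.onsets]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("onsets must be strictly increasing")
        labels = [lab for _, lab in self.onsets]
        if labels.count("ws") != 1:
            raise ValueError("exactly one WS per trial")
        n_targets = labels.count("target")
        if self.validity is Validity.CATCH:
            if n_targets != 0:
                raise ValueError("catch trials carry no target")
        elif n_targets != 1:
            raise ValueError("non-catch trials carry exactly one target")

    @property
    def ws_time(self) -> int:
        return next(t for t, lab in self.onsets if lab == "ws")

    @property
    def target_time(self) -> int | None:
        return next((t for t, lab in self.onsets if lab == "target"), None)

    @property
    def target_soa(self) -> int | None:
        t = self.target_time
        return None if t is None else t - self.ws_time

    @property
    def onset_times(self) -> list[int]:
        return [t for t, _ in self.onsets]


@dataclass
class BlockSpec:
    condition: Condition
    trials: list[TrialSpec]
    size: int = 32


@dataclass
class ImpulseTrain:
    """Binary event time series at 1 kHz driving the entrainment model."""

    fs: int
    values: np.ndarray
    onsets_idx: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.onsets_idx = np.asarray(self.onsets_idx, dtype=int)


@dataclass
class SequenceSummary:
    freqs: np.ndarray | None = None
    amplitude: np.ndarray | None = None
    lags: np.ndarray | None = None
    acf: np.ndarray | None = None


def _check_enum(value, enum_cls):
    try:
        return enum_cls(value)
    except ValueError as exc:
        allowed = ", ".join(e.value for e in enum_cls)
        raise ValueError(f"invalid {enum_cls.__name__} {value!r}; expected one of: {allowed}") from exc


def generate_trial(
    condition: Condition | str,
    cue_soa: int,
    validity: Validity | str,
    n_pre_ws: int,
    rng: np.random.Generator,
) -> TrialSpec:
    """Generate one trial's onset schedule.

    The WS-target SOA equals ``cue_soa`` in valid trials and the other SOA in
    invalid trials; in the Random condition it is drawn from the jittered
    short or long distribution.  Catch trials end with a 1500 ms blank after
    the WS.
    """
    condition = _check_enum(condition, Condition)
    validity = _check_enum(validity, Validity)
    cue_soa = int(cue_soa)
    other_soa(cue_soa)  # validates
    if n_pre_ws not in N_PRE_WS_CHOICES:
        raise ValueError(f"n_pre_ws must be in {N_PRE_WS_CHOICES}, got {n_pre_ws}")

    onsets: list[tuple[int, str]] = []
    t = 0
    if condition is Condition.RHYTHMIC:
        for _ in range(n_pre_ws):
            onsets.append((t, "stream_black"))
            t += cue_soa
        ws_time = t
    elif condition is Condition.REPEATED_INTERVAL:
        jitter = REPEATED_JITTER[cue_soa]
        for _ in range(n_pre_ws):
            onsets.append((t, "stream_black"))
            onsets.append((t + cue_soa, "stream_red"))
            t = t + cue_soa + int(rng.choice(jitter))
        ws_time = t
    else:  # Random
        for _ in range(n_pre_ws):
            onsets.append((t, "stream_black"))
            t += cue_soa + int(rng.choice(RANDOM_JITTER))
        ws_time = t
    onsets.append((ws_time, "ws"))

    if validity is Validity.CATCH:
        end = ws_time + CATCH_BLANK_MS
    else:
        if condition is Condition.RANDOM:
            base = cue_soa if validity is Validity.VALID else other_soa(cue_soa)
            soa = base + int(rng.choice(RANDOM_JITTER))
        else:
            soa = cue_soa if validity is Validity.VALID else other_soa(cue_soa)
        onsets.append((ws_time + soa, "target"))
        end = ws_time + soa + CATCH_BLANK_MS

    return TrialSpec(
        condition=condition,
        cue_soa=cue_soa,
        validity=validity,
        n_pre_ws=n_pre_ws,
        onsets=onsets,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        end_ms=end,
    )


def _block_counts(condition: Condition, size: int) -> dict[Validity, int]:
    props = RANDOM_PROPORTIONS if condition is Condition.RANDOM else PREDICTIVE_PROPORTIONS
    counts = {}
    for val, p in props.items():
        c = size * p
        if abs(c - round(c)) > 1e-9:
            raise ValueError(
                f"block size {size} does not yield integer trial counts for {condition.value}"
            )
        counts[val] = int(round(c))
    return counts


def generate_block(
    condition: Condition | str,
    size: int = 32,
    rng: np.random.Generator | None = None,
) -> BlockSpec:
    """Generate one block with exact validity proportions.

    Predictive conditions: 75% valid / 12.5% invalid / 12.5% catch.  Random:
    43.75% / 43.75% / 12.5%.  Each validity cell is split evenly between
    short- and long-cue trials; trial order is randomised.
    """
    condition = _check_enum(condition, Condition)
    rng = np.random.default_rng() if rng is None else rng
    counts = _block_counts(condition, size)
    plan: list[tuple[int, Validity]] = []
    for val, c in counts.items():
        if c % 2:
            raise ValueError(f"validity count {c} cannot be split across the two cue SOAs")
        plan += [(SHORT_SOA_MS, val)] * (c // 2) + [(LONG_SOA_MS, val)] * (c // 2)
    order = rng.permutation(len(plan))
    trials = [
        generate_trial(condition, plan[i][0], plan[i][1], int(rng.choice(N_PRE_WS_CHOICES)), rng)
        for i in order
    ]
    return BlockSpec(condition=condition, trials=trials, size=size)


def generate_session(
    rng: np.random.Generator | None = None,
    block_size: int = 32,
    repeated_interval_first: bool = True,
) -> list[BlockSpec]:
    """Generate a full session: two Random blocks, then Repeated-Interval and
    Rhythmic blocks alternating (four each; which starts is counterbalanced).
    """
    rng = np.random.default_rng() if rng is None else rng
    blocks = [generate_block(Condition.RANDOM, block_size, rng) for _ in range(2)]
    pair = (Condition.REPEATED_INTERVAL, Condition.RHYTHMIC)
    if not repeated_interval_first:
        pair = pair[::-1]
    for _ in range(4):
        for cond in pair:
            blocks.append(generate_block(cond, block_size, rng))
    return blocks


def session_trials(blocks: Iterable[BlockSpec]) -> list[TrialSpec]:
    return [t for b in blocks for t in b.trials]


def to_impulse_train(
    trials: Sequence[TrialSpec],
    fs: int = 1000,
    fixation_ms: int = FIXATION_MS,
    inter_trial_ms: int | tuple[int, int] = 1000,
    rng: np.random.Generator | None = None,
) -> ImpulseTrain:
    """Concatenate trials into a binary impulse train (one at every onset).

    Each trial is preceded by the fixation interval and followed by the
    inter-trial gap; the per-sample value is 1 at stimulus onsets (stream,
    WS and target) and 0 otherwise.  ``inter_trial_ms`` may be a (lo, hi)
    range sampled uniformly per trial -- a fixed gap imprints a spurious
    comb periodicity on the concatenated train, so jittered gaps are
    recommended for spectral summaries.
    """
    step = 1000 // fs
    if not isinstance(inter_trial_ms, (int, np.integer)):
        lo, hi = inter_trial_ms
        rng = np.random.default_rng(0) if rng is None else rng
        gaps = [int(rng.integers(lo, hi + 1)) for _ in trials]
    else:
        gaps = [int(inter_trial_ms)] * len(trials)
    onsets_idx: list[int] = []
    cursor = 0
    for trial, gap in zip(trials, gaps):
        cursor += fixation_ms
        onsets_idx.extend((cursor + t) // step for t in trial.onset_times)
        cursor += trial.end_ms + gap
    n = cursor // step + 1
    values = np.zeros(max(n, 0), dtype=np.int8)
    idx = np.asarray(onsets_idx, dtype=int)
    values[idx] = 1
    return ImpulseTrain(fs=fs, values=values, onsets_idx=idx)


def trial_impulse_train(trial: TrialSpec, fs: int = 1000, pad_ms: int = 0) -> ImpulseTrain:
    """Impulse train of a single trial (no fixation offset), optionally padded."""
    step = 1000 // fs
    idx = np.asarray([t // step for t in trial.onset_times], dtype=int)
    values = np.zeros(trial.end_ms // step + pad_ms // step + 1, dtype=np.int8)
    values[idx] = 1
    return ImpulseTrain(fs=fs, values=values, onsets_idx=idx)


def sequence_spectrum(
    train: ImpulseTrain, fmax: float = 5.0, normalize: bool = False
) -> SequenceSummary:
    """Magnitude spectrum of the binary train on a 0..``fmax`` Hz grid.

    ``normalize=True`` divides by the train length, making amplitudes
    comparable between conditions whose trains differ in duration.
    """
    x = np.asarray(train.values, dtype=float)
    if x.size == 0:
        raise ValueError("empty impulse train")
    spec = np.abs(np.fft.rfft(x))
    if normalize:
        spec = spec / x.size
    freqs = np.fft.rfftfreq(x.size, d=1.0 / train.fs)
    keep = freqs <= fmax
    return SequenceSummary(freqs=freqs[keep], amplitude=spec[keep])


def sequence_autocorrelation(train: ImpulseTrain, max_lag_ms: int = 5000) -> SequenceSummary:
    """Normalised autocorrelation of the train on lags 0..``max_lag_ms``."""
    x = np.asarray(train.values, dtype=float)
    if x.size == 0:
        raise ValueError("empty impulse train")
    x = x - x.mean()
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    X = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(X * np.conj(X))[: n]
    acf /= acf[0]
    max_lag = min(int(max_lag_ms * train.fs / 1000), n - 1)
    lags = np.arange(max_lag + 1) * (1000 / train.fs)
    return SequenceSummary(lags=lags, acf=acf[: max_lag + 1])


# ---------------------------------------------------------------------------
# tabular I/O

EVENT_COLUMNS = [
    "trial_id", "block", "condition", "cue_soa_ms", "validity",
    "n_pre_ws", "onset_label", "onset_ms",
]


def trials_to_table(blocks: Sequence[BlockSpec]) -> pd.DataFrame:
    """Long-format event table (one row per onset) for a list of blocks."""
    rows = []
    trial_id = 0
    for bi, block in enumerate(blocks):
        for trial in block.trials:
            for t, lab in trial.onsets:
                rows.append(
                    dict(
                        trial_id=trial_id,
                        block=bi,
                        condition=trial.condition.value,
                        cue_soa_ms=trial.cue_soa,
                        validity=trial.validity.value,
                        n_pre_ws=trial.n_pre_ws,
                        onset_label=lab,
                        onset_ms=t,
                    )
                )
            trial_id += 1
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_trial_table(blocks: Sequence[BlockSpec], path) -> None:
    trials_to_table(blocks).to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def table_to_trials(table: pd.DataFrame) -> list[TrialSpec]:
    """Rebuild TrialSpec objects from a long-format event table."""
    trials = []
    for (_, _), grp in table.groupby(["trial_id", "block"], sort=True):
        first = grp.iloc[0]
        onsets = [(int(r.onset_ms), str(r.onset_label)) for r in grp.itertuples()]
        onsets.sort()
        trials.append(
            TrialSpec(
                condition=Condition(first.condition),
                cue_soa=int(first.cue_soa_ms),
                validity=Validity(first.validity),
                n_pre_ws=int(first.n_pre_ws),
                onsets=onsets,
                end_ms=onsets[-1][0] + CATCH_BLANK_MS,
            )
        )
    return trials
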