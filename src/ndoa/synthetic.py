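"""Synthetic EEG data logs with the statistical structure the pipeline
assumes, so every stage is testable without clinical recordings.

The generator emulates the contrast the index exploits: awake EEG is
low-voltage (peaks around ±15 µV) and broadband with dominant 8–30 Hz
power; deep anaesthesia is high-voltage (peaks around ±60 µV) and dominated
by 0.5–4 Hz slow waves. Intermediate states interpolate. On top of the state
signal it injects the monitor's nuisance phenomena: isolated spikes,
low-amplitude noise episodes, 30–60 Hz EMG bursts, and SQI dropouts during
which the reference index carries the −3276.8 sentinel. The per-second
reference trace follows conventional clinical index bands per state
(awake≈90 … deep≈30), smoothed and jittered; its job is ordinal structure,
not clinical realism. Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.signal

from .datalog import (BIS_SENTINEL, DEFAULT_FS, AnnotatedRecord, DataLog,
                      EEGRecording)
from .errors import NdoaError

STATE_INDEX_LEVELS = {"awake": 90.0, "light": 65.0, "moderate": 50.0,
                      "deep": 30.0}

#: Per-state component amplitudes (µV std): (slow 0.5-4 Hz, mid 8-30 Hz).
STATE_BAND_STD = {
    "awake": (1.5, 4.5),
    "light": (4.0, 3.5),
    "moderate": (8.0, 3.0),
    "deep": (18.0, 1.5),
}

#: Small broadband floor present in every state (µV std).
_BROADBAND_STD = 0.8


@dataclass
class StateSchedule:
    """Ordered (state, duration s) segments with per-state index levels."""

    segments: list[tuple[str, int]]
    target_index: dict = field(
        default_factory=lambda: dict(STATE_INDEX_LEVELS))

    def __post_init__(self) -> None:
        if not self.segments:
            raise NdoaError("schedule needs at least one segment")
        for state, dur in self.segments:
            if state not in STATE_BAND_STD:
                raise NdoaError(f"unknown state {state!r}")
            if dur < 10:
                raise NdoaError(f"segment durations must be >= 10 s, "
                                f"got {dur}")
        if self.duration_s < 60:
            raise NdoaError("total schedule duration must be >= 60 s")

    @property
    def duration_s(self) -> int:
        return int(sum(d for _, d in self.segments))

    def spans(self) -> list[tuple[str, int, int]]:
        """(state, start_s, end_s) half-open spans."""
        out, t = [], 0
        for state, dur in self.segments:
            out.append((state, t, t + dur))
            t += dur
        return out

    def state_per_second(self) -> list[str]:
        out = []
        for state, dur in self.segments:
            out.extend([state] * dur)
        return out


@dataclass
class NoiseSpec:
    """Nuisance phenomena injected on top of the state signal.

    ``spike_rate_per_min`` isolated spikes of ``spike_multiplier`` times the
    local rms; ``low_amp_rate_per_min`` episodes (3 s) during which the
    signal collapses to ``low_amp_fraction`` of its amplitude; ``emg_bursts``
    spans (start_s, duration_s) of added 30–60 Hz power at
    ``emg_multiplier`` times the mid-band amplitude; ``sqi_dropouts`` spans
    (start_s, duration_s) during which SQI = 10 and the reference carries
    the sentinel.
    """

    spike_rate_per_min: float = 2.0
    spike_multiplier: float = 8.0
    low_amp_rate_per_min: float = 0.5
    low_amp_fraction: float = 0.15
    emg_bursts: list[tuple[int, int]] = field(default_factory=list)
    emg_multiplier: float = 4.0
    sqi_dropouts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.spike_rate_per_min < 0 or self.low_amp_rate_per_min < 0
                or self.spike_multiplier < 0):
            raise NdoaError("noise rates and multipliers must be >= 0")


def _bandpass(white: np.ndarray, lo: float, hi: float, fs: float,
              order: int = 4) -> np.ndarray:
    sos = scipy.signal.butter(order, [lo, hi], btype="band", fs=fs,
                              output="sos")
    y = scipy.signal.sosfiltfilt(sos, white)
    sd = y.std()
    return y / sd if sd > 0 else y


def generate(schedule: StateSchedule, noise: NoiseSpec | None = None,
             seed: int = 0, subject_id: str | None = None,
             fs: float = DEFAULT_FS) -> DataLog:
    """Generate one synthetic data log. Deterministic per seed."""
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    n_sec = schedule.duration_s
    n = int(n_sec * fs)
    for start, dur in list(noise.emg_bursts) + list(noise.sqi_dropouts):
        if start < 0 or start + dur > n_sec:
            raise NdoaError("noise span outside record duration")

    # state-dependent amplitude envelopes, crossfaded over ~5 s
    states = schedule.state_per_second()
    slow_sec = np.array([STATE_BAND_STD[s][0] for s in states])
    mid_sec = np.array([STATE_BAND_STD[s][1] for s in states])
    slow_env = scipy.ndimage.gaussian_filter1d(slow_sec, 2.0, mode="nearest")
    mid_env = scipy.ndimage.gaussian_filter1d(mid_sec, 2.0, mode="nearest")
    slow_env = np.repeat(slow_env, int(fs))
    mid_env = np.repeat(mid_env, int(fs))

    slow = _bandpass(rng.standard_normal(n), 0.5, 4.0, fs) * slow_env
    mid = _bandpass(rng.standard_normal(n), 8.0, 30.0, fs) * mid_env
    broad = _bandpass(rng.standard_normal(n), 0.5, 47.0, fs) * _BROADBAND_STD
    x = slow + mid + broad

    # EMG bursts: added 30-60 Hz power scaled to the awake mid-band level
    emg_env = np.zeros(n)
    for start, dur in noise.emg_bursts:
        emg_env[int(start * fs):int((start + dur) * fs)] = 1.0
    if np.any(emg_env > 0):
        emg = _bandpass(rng.standard_normal(n), 30.0, 60.0, fs)
        x = x + emg * emg_env * noise.emg_multiplier * STATE_BAND_STD[
            "awake"][1]

    # low-amplitude noise episodes: the signal collapses for ~3 s
    n_low = rng.poisson(noise.low_amp_rate_per_min * n_sec / 60.0)
    low_spans = []
    for _ in range(n_low):
        start = int(rng.integers(0, max(1, n_sec - 3)))
        low_spans.append((start, 3))
        sl = slice(int(start * fs), int((start + 3) * fs))
        x[sl] = x[sl] * noise.low_amp_fraction
    # isolated spikes: single samples at spike_multiplier x local rms
    n_spikes = rng.poisson(noise.spike_rate_per_min * n_sec / 60.0)
    spike_pos = rng.integers(int(fs), n - int(fs), size=n_spikes)
    for pos in spike_pos:
        local = x[pos - int(fs) // 2: pos + int(fs) // 2]
        rms = float(np.sqrt(np.mean(local ** 2)))
        x[pos] = float(rng.choice([-1.0, 1.0])) * noise.spike_multiplier * rms

    # per-second annotations
    target = np.array([schedule.target_index[s] for s in states])
    bis = scipy.ndimage.gaussian_filter1d(target, 3.0, mode="nearest")
    bis = np.clip(bis + rng.normal(0.0, 3.0, size=n_sec), 0.0, 100.0)
    sqi = np.full(n_sec, 95.0)
    emg_idx = np.clip(rng.normal(3.0, 1.0, size=n_sec), 0.0, None)
    for start, dur in noise.emg_bursts:
        emg_idx[start:start + dur] += 40.0
    for start, dur in noise.sqi_dropouts:
        sqi[start:start + dur] = 10.0
        bis[start:start + dur] = BIS_SENTINEL

    if subject_id is None:
        subject_id = f"SYN{seed:08d}"
    annotations = [AnnotatedRecord(t=t, bis=float(bis[t]), sqi=float(sqi[t]),
                                   emg=float(emg_idx[t]))
                   for t in range(n_sec)]
    log = DataLog(
        recording=EEGRecording(samples=x, fs=fs, subject_id=subject_id,
                               channel="CH2"),
        annotations=annotations,
    )
    log.validate()
    return log


def sinusoid_spike_fixture(seed: int, n: int = 1280, fs: float = DEFAULT_FS):
    """A clean low-frequency sinusoid plus one large spike.

    Returns ``(clean, noisy)``: a 1-3 Hz sinusoid of 30-60 µV amplitude
    (random phase) and the same signal with a single-sample spike of 10x the
    sinusoid amplitude at a random interior position — the denoiser's
    canonical spike-suppression fixture family.
    """
    rng = np.random.default_rng(seed)
    freq = rng.uniform(1.0, 3.0)
    amp = rng.uniform(30.0, 60.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / fs
    clean = amp * np.sin(2.0 * np.pi * freq * t + phase)
    noisy = clean.copy()
    pos = int(rng.integers(n // 8, 7 * n // 8))
    noisy[pos] += float(rng.choice([-1.0, 1.0])) * 10.0 * amp
    return clean, noisy


def default_schedule(rng: np.random.Generator) -> StateSchedule:
    """A varied induction -> maintenance -> emergence schedule (~150-200 s)."""
    return StateSchedule(segments=[
        ("awake", int(rng.integers(30, 41))),
        ("light", int(rng.integers(20, 31))),
        ("moderate", int(rng.integers(20, 31))),
        ("deep", int(rng.integers(45, 61))),
        ("moderate", int(rng.integers(15, 26))),
        ("awake", int(rng.integers(15, 26))),
    ])


def make_benchmark(n_records: int = 10, seed: int = 7,
                   train_fraction: float = 60.0 / 73.0):
    """Generate a benchmark of varied records plus a manifest.

    Returns ``(logs, manifest)``. The manifest records per-record seeds,
    schedules, noise settings and the train/test assignment (train count =
    round(n * 60/73), mirroring a 60/13-subject split proportionally);
    regenerating from the manifest reproduces identical records.
    """
    if n_records < 2:
        raise NdoaError("benchmark needs >= 2 records")
    rng = np.random.default_rng(seed)
    n_train = int(round(n_records * train_fraction))
    n_train = min(max(n_train, 1), n_records - 1)
    logs, entries = [], []
    for i in range(n_records):
        rec_seed = int(rng.integers(0, 2 ** 31))
        sched = default_schedule(rng)
        noise = NoiseSpec()
        if i % 2 == 0:  # half the records carry an EMG burst in deep sleep
            deep = [s for s in sched.spans() if s[0] == "deep"][0]
            noise.emg_bursts = [(deep[1] + 5, 20)]
        if i % 3 == 0:  # a third carry an SQI dropout span
            mod = [s for s in sched.spans() if s[0] == "moderate"][0]
            noise.sqi_dropouts = [(mod[1] + 2, min(12, mod[2] - mod[1] - 2))]
        sid = f"SYN{seed:03d}_{i:02d}"
        logs.append(generate(sched, noise, seed=rec_seed, subject_id=sid))
        entries.append({
            "subject_id": sid,
            "seed": rec_seed,
            "train": i < n_train,
            "schedule": [[s, d] for s, d in sched.segments],
            "noise": {
                "spike_rate_per_min": noise.spike_rate_per_min,
                "spike_multiplier": noise.spike_multiplier,
                "low_amp_rate_per_min": noise.low_amp_rate_per_min,
                "low_amp_fraction": noise.low_amp_fraction,
                "emg_bursts": [list(b) for b in noise.emg_bursts],
                "emg_multiplier": noise.emg_multiplier,
                "sqi_dropouts": [list(b) for b in noise.sqi_dropouts],
            },
        })
    manifest = {"seed": seed, "n_records": n_records, "n_train": n_train,
                "records": entries}
    return logs, manifest
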