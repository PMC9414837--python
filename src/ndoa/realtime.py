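"""Per-second streaming of the index: denoise -> features -> predict -> tune.

A 10 s window slides over the EEG with a 1 s step (9 s overlap). The first
four seconds are a startup delay with no output; from the fifth second the
engine processes the trailing buffer (which grows from 5 s to the full 10 s
window) and emits one value per second. The raw model output is smoothed by

    tuned_t = 0.8 * mean(raw history of the last <= 4 s) + 0.2 * raw_t

which bounds the per-second excursion and suppresses transient artefacts
(e.g. EMG bursts) without adding display latency. The index is emitted at
every second regardless of the reference monitor's validity — that is the
point of the SQI-dropout behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datalog import DataLog
from .errors import NdoaError
from .features import EntropyParams, PSDFeatureParams, extract_features
from .preprocess import DenoiseConfig, denoise_with_config
from .regression import INDEX_MAX, INDEX_MIN, IndexModel, predict

WINDOW_S = 10
STARTUP_DELAY_S = 4
HISTORY_LEN = 4
W_PREV, W_CUR = 0.8, 0.2


@dataclass
class StreamState:
    """Mutable state of the streaming engine: trailing sample buffer, recent
    per-second index history and the current second."""

    buffer: np.ndarray = field(default_factory=lambda: np.empty(0))
    recent: list = field(default_factory=list)
    t: int = -1  # last completed second; -1 before any data


@dataclass
class IndexTraceEntry:
    t: int
    raw: float
    tuned: float
    valid: bool


@dataclass
class IndexTrace:
    """Per-second index trace: raw model output, tuned output, validity."""

    t: np.ndarray
    raw: np.ndarray
    tuned: np.ndarray
    valid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "raw": self.raw,
                             "tuned": self.tuned,
                             "valid": self.valid.astype(int)})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read(cls, path) -> "IndexTrace":
        df = pd.read_csv(path)
        return cls(t=df["t_s"].to_numpy(int), raw=df["raw"].to_numpy(float),
                   tuned=df["tuned"].to_numpy(float),
                   valid=df["valid"].to_numpy(bool))


def tune(recent_raw, current_raw: float,
         w_prev: float = W_PREV, w_cur: float = W_CUR) -> float:
    """One step of the output smoother, clamped to [0, 100].

    ``recent_raw`` holds the raw per-second values of (up to) the last four
    seconds; with an empty history the current value passes through — the
    caller flags that condition if it matters.
    """
    recent_raw = list(recent_raw)
    if len(recent_raw) > HISTORY_LEN:
        raise NdoaError(f"history holds at most {HISTORY_LEN} values")
    if not recent_raw:
        out = current_raw
    else:
        out = w_prev * float(np.mean(recent_raw)) + w_cur * current_raw
    return float(np.clip(out, INDEX_MIN, INDEX_MAX))


def _process_window(window: np.ndarray, model: IndexModel,
                    denoise_config: DenoiseConfig,
                    entropy_params: EntropyParams | None,
                    psd_params: PSDFeatureParams | None) -> float:
    """Denoise one trailing window, extract features, predict one raw value;
    NaN signals a degenerate window."""
    clean = denoise_with_config(window, denoise_config)
    fv = extract_features(clean, entropy_params=entropy_params,
                          psd_params=psd_params)
    if fv.degenerate:
        return float("nan")
    return float(predict(model, fv.as_array().reshape(1, -1))[0])


def _configs_from_model(model: IndexModel):
    cfg = model.pipeline_config or {}
    dn = DenoiseConfig.from_dict(cfg["denoise"]) if "denoise" in cfg \
        else DenoiseConfig()
    return dn, None, None  # entropy/psd params at package defaults


def step(state: StreamState, one_second: np.ndarray, model: IndexModel,
         fs: float = 128.0,
         history_mode: str = "raw") -> tuple[StreamState, IndexTraceEntry]:
    """Advance the stream by one second of samples.

    Returns the updated state and the emitted trace entry. Seconds 0-3 are
    the startup delay (invalid entries); afterwards the trailing
    ``min(buffered, 10 s)`` window is processed. ``history_mode`` selects
    whether the smoother's history stores raw (default) or tuned values.
    """
    one_second = np.asarray(one_second, dtype=float)
    n_fs = int(round(fs))
    if one_second.size != n_fs:
        raise NdoaError(f"step expects exactly {n_fs} samples, got "
                        f"{one_second.size}")
    buffer = np.concatenate([state.buffer, one_second])[-WINDOW_S * n_fs:]
    t = state.t + 1
    recent = list(state.recent)
    if t < STARTUP_DELAY_S:
        entry = IndexTraceEntry(t=t, raw=float("nan"), tuned=float("nan"),
                                valid=False)
    else:
        dn_cfg, ep, pp = _configs_from_model(model)
        raw = _process_window(buffer, model, dn_cfg, ep, pp)
        if np.isnan(raw):
            entry = IndexTraceEntry(t=t, raw=raw, tuned=float("nan"),
                                    valid=False)
        else:
            tuned = tune(recent, raw)
            recent = (recent + [raw if history_mode == "raw" else tuned]
                      )[-HISTORY_LEN:]
            entry = IndexTraceEntry(t=t, raw=raw, tuned=tuned, valid=True)
    return StreamState(buffer=buffer, recent=recent, t=t), entry


def run_record(log: DataLog, model: IndexModel,
               history_mode: str = "raw") -> IndexTrace:
    """Whole-record (batch) execution; identical output to the step-wise
    stream by construction (same per-window path, same smoother roll-out).
    """
    fs = int(round(log.recording.fs))
    n_sec = log.n_seconds
    dn_cfg, ep, pp = _configs_from_model(model)
    samples = log.recording.samples
    t_arr = np.arange(n_sec)
    raw = np.full(n_sec, np.nan)
    tuned = np.full(n_sec, np.nan)
    valid = np.zeros(n_sec, dtype=bool)
    recent: list[float] = []
    for t in range(STARTUP_DELAY_S, n_sec):
        lo = max(0, (t + 1) * fs - WINDOW_S * fs)
        window = samples[lo:(t + 1) * fs]
        r = _process_window(window, model, dn_cfg, ep, pp)
        raw[t] = r
        if np.isnan(r):
            continue
        tuned[t] = tune(recent, r)
        recent = (recent + [r if history_mode == "raw" else tuned[t]]
                  )[-HISTORY_LEN:]
        valid[t] = True
    return IndexTrace(t=t_arr, raw=raw, tuned=tuned, valid=valid)


def feature_table(log: DataLog, denoise_config: DenoiseConfig | None = None,
                  entropy_params: EntropyParams | None = None,
                  psd_params: PSDFeatureParams | None = None) -> pd.DataFrame:
    """Per-second feature table over full 10 s windows (training path).

    Second ``t`` gets the features of the denoised window covering samples
    ``[(t+1-10)*fs, (t+1)*fs)``; the first nine seconds, which lack a full
    window, are omitted. Columns: ``t_s``, the five features,
    ``degenerate_flag``.
    """
    dn_cfg = denoise_config or DenoiseConfig()
    fs = int(round(log.recording.fs))
    samples = log.recording.samples
    rows = []
    for t in range(WINDOW_S - 1, log.n_seconds):
        window = samples[(t + 1 - WINDOW_S) * fs:(t + 1) * fs]
        clean = denoise_with_config(window, dn_cfg)
        fv = extract_features(clean, entropy_params=entropy_params,
                              psd_params=psd_params)
        rows.append((t, fv.se, fv.fe, fv.pe, fv.hurst_rr, fv.psd_fea,
                     int(fv.degenerate)))
    return pd.DataFrame(rows, columns=["t_s", "se", "fe", "pe", "hurst_rr",
                                       "psd_fea", "degenerate_flag"])


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=False, float_format="%.10g")
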