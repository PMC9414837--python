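"""Agreement and correlation between the streamed index and the reference.

Bland–Altman analysis uses the paired differences d = index − reference on
valid seconds only: bias = mean(d), sd = std(d) (sample convention, n−1),
limits of agreement bias ± 2·sd, and the agreement rate is the percentage of
differences inside those limits (≈95.45% for normal d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datalog import DataLog, valid_bis_mask
from .errors import DegenerateSignalError, NdoaError
from .realtime import IndexTrace

DEFAULT_SD_MULTIPLIER = 2.0


@dataclass
class AgreementReport:
    """Bland–Altman summary plus the Pearson correlation of the pairs."""

    pearson_r: float
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    agreement_pct: float
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def pearson(x, y) -> float:
    """Pearson correlation coefficient of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise NdoaError("need equal-length sequences of >= 3 values")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateSignalError("constant input: correlation undefined")
    return float(scipy.stats.pearsonr(x, y).statistic)


def bland_altman(ndoa, ref, valid=None,
                 sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
                 ddof: int = 1) -> AgreementReport:
    """Bland–Altman agreement between an index trace and its reference.

    ``valid`` masks the pairs that enter the analysis (e.g. reference
    sentinel / low-SQI seconds excluded); at least 3 valid pairs are
    required. ``ddof=1`` selects the sample standard deviation; ``ddof=0``
    the population convention.
    """
    ndoa = np.asarray(ndoa, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if ndoa.size != ref.size:
        raise NdoaError("sequences must have equal length")
    if valid is None:
        valid = np.ones(ndoa.size, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    d = ndoa[valid] - ref[valid]
    if d.size < 3:
        raise NdoaError(f"need >= 3 valid pairs, got {d.size}")
    bias = float(d.mean())
    sd = float(d.std(ddof=ddof))
    lo = bias - sd_multiplier * sd
    hi = bias + sd_multiplier * sd
    inside = np.count_nonzero((d >= lo) & (d <= hi))
    try:
        r = pearson(ndoa[valid], ref[valid])
    except DegenerateSignalError:
        r = float("nan")
    return AgreementReport(
        pearson_r=r, bias=bias, sd=sd, loa_lower=lo, loa_upper=hi,
        agreement_pct=100.0 * inside / d.size, n=int(d.size),
    )


def per_subject_report(traces: dict[str, IndexTrace],
                       logs: dict[str, DataLog]) -> pd.DataFrame:
    """Per-subject correlation table plus a final average row.

    One row per subject (sorted by id) with the Pearson correlation between
    the tuned index and the reference over seconds valid on both sides, and
    a terminal ``average`` row carrying the arithmetic mean of the
    per-subject correlations and the total pair count.
    """
    if set(traces) != set(logs):
        raise NdoaError("trace and log subject sets differ: "
                        f"{sorted(set(traces) ^ set(logs))}")
    rows = []
    for sid in sorted(traces):
        trace, log = traces[sid], logs[sid]
        ann = log.annotation_frame()
        mask = valid_bis_mask(ann) & trace.valid
        r = pearson(trace.tuned[mask], ann["bis"].to_numpy()[mask])
        rows.append({"subject": sid, "pearson_r": r,
                     "n": int(np.count_nonzero(mask))})
    avg = {"subject": "average",
           "pearson_r": float(np.mean([r["pearson_r"] for r in rows])),
           "n": int(np.sum([r["n"] for r in rows]))}
    return pd.DataFrame(rows + [avg])
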