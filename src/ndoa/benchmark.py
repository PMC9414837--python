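"""End-to-end evaluation of the pipeline on the synthetic benchmark.

Ties the other modules together: generate a benchmark of records, extract
training features, fit the Gaussian-process index model, stream every record
through the real-time engine with a model that never saw it (record-wise
2-fold cross-fitting, so each trace is genuinely held-out), and score the
result — per-record correlation with the reference, awake/deep separation of
the tuned index, pooled Bland–Altman agreement, and cross-validated fit
metrics for the model menu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datalog import valid_bis_mask
from .evaluation import AgreementReport, bland_altman, pearson
from .realtime import STARTUP_DELAY_S, feature_table, run_record
from .regression import FitMetrics, build_training_set, crossvalidate, fit
from .synthetic import StateSchedule, make_benchmark


@dataclass
class BenchmarkResult:
    per_record: pd.DataFrame       # subject, pearson_r, awake/deep means, n
    agreement: AgreementReport     # pooled over all held-out seconds
    cv: dict[str, FitMetrics]      # model kind -> fivefold CV metrics


def _span_mean(trace, spans, state, usable):
    vals = []
    for s, lo, hi in spans:
        if s != state:
            continue
        sel = usable & (np.arange(trace.tuned.size) >= lo) \
            & (np.arange(trace.tuned.size) < hi)
        vals.extend(trace.tuned[sel].tolist())
    return float(np.mean(vals)) if vals else float("nan")


def evaluate_benchmark(n_records: int = 10, seed: int = 7,
                       subset_cap: int = 1000,
                       cv_kinds: tuple = ("sq_exp_gp", "linear_robust"),
                       cv_folds: int = 5) -> BenchmarkResult:
    """Run the full pipeline on a fresh benchmark and score it.

    Held-out traces come from 2-fold cross-fitting over records: the
    records are split in half (seeded), each half is streamed through a
    model trained on the other half. CV metrics are computed row-wise on
    the manifest's train-split feature rows for each requested model kind.
    """
    logs, manifest = make_benchmark(n_records=n_records, seed=seed)
    tables = {log.recording.subject_id: feature_table(log) for log in logs}

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_records)
    half = n_records // 2
    folds = [order[:half], order[half:]]

    models = []
    for k in (0, 1):
        train_logs = [logs[i] for i in folds[1 - k]]
        ts = build_training_set(train_logs, tables)
        models.append(fit(ts, kind="sq_exp_gp", seed=seed,
                          subset_cap=subset_cap))

    rows, tuned_all, ref_all = [], [], []
    for k in (0, 1):
        for i in folds[k]:
            log = logs[i]
            trace = run_record(log, models[k])
            ann = log.annotation_frame()
            mask = valid_bis_mask(ann) & trace.valid
            bis = ann["bis"].to_numpy()
            r = pearson(trace.tuned[mask], bis[mask])
            sched = StateSchedule(
                segments=[tuple(s) for s in
                          manifest["records"][i]["schedule"]])
            usable = trace.valid.copy()
            usable[:STARTUP_DELAY_S] = False
            rows.append({
                "subject": log.recording.subject_id,
                "pearson_r": r,
                "awake_mean": _span_mean(trace, sched.spans(), "awake",
                                         usable),
                "deep_mean": _span_mean(trace, sched.spans(), "deep",
                                        usable),
                "n": int(np.count_nonzero(mask)),
            })
            tuned_all.append(trace.tuned[mask])
            ref_all.append(bis[mask])

    agreement = bland_altman(np.concatenate(tuned_all),
                             np.concatenate(ref_all))

    train_ids = {e["subject_id"] for e in manifest["records"] if e["train"]}
    train_logs = [lg for lg in logs if lg.recording.subject_id in train_ids]
    ts = build_training_set(train_logs, tables)
    cv = {kind: crossvalidate(ts, kind=kind, folds=cv_folds, seed=seed,
                              subset_cap=subset_cap)
          for kind in cv_kinds}

    per_record = pd.DataFrame(rows).sort_values("subject",
                                                ignore_index=True)
    return BenchmarkResult(per_record=per_record, agreement=agreement,
                           cv=cv)
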