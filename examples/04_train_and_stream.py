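"""Train the Gaussian-process index model and stream a held-out record.

Trains on two synthetic records, then runs a third, never-seen record
through the per-second real-time engine and scores the tuned index against
the record's own reference trace."""

import numpy as np

from ndoa import (StateSchedule, bland_altman, build_training_set,
                  crossvalidate, feature_table, fit, generate, run_record,
                  valid_bis_mask)
from ndoa.synthetic import default_schedule

rng = np.random.default_rng(5)
train_logs = [generate(default_schedule(rng), seed=s, subject_id=f"train{s}")
              for s in (101, 102)]
test_log = generate(default_schedule(rng), seed=103, subject_id="test")

tables = {lg.recording.subject_id: feature_table(lg) for lg in train_logs}
train = build_training_set(train_logs, tables)
print(f"training rows: {train.n}")

cv = crossvalidate(train, kind="sq_exp_gp", folds=5, seed=0)
print(f"fivefold CV:  R2 {cv.r2:.3f}  RMSE {cv.rmse:.2f}  MAE {cv.mae:.2f}")

model = fit(train, kind="sq_exp_gp", seed=0)
trace = run_record(test_log, model)

ann = test_log.annotation_frame()
mask = valid_bis_mask(ann) & trace.valid
rep = bland_altman(trace.tuned, ann["bis"].to_numpy(), valid=mask)
print(f"held-out record: r {rep.pearson_r:.3f}  bias {rep.bias:+.2f}  "
      f"limits [{rep.loa_lower:.2f}, {rep.loa_upper:.2f}]  "
      f"agreement {rep.agreement_pct:.1f}% (n={rep.n})")
print("first 8 seconds of the trace (the 4 s startup delay is invalid):")
print(trace.to_frame().head(8).to_string(index=False))
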