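"""Generate a synthetic anaesthesia EEG record and inspect its structure.

Builds a 150 s awake -> deep -> awake record with an SQI dropout, prints the
per-state amplitude and band-power contrast, and shows how the reference
index behaves through the dropout (the -3276.8 sentinel)."""

import numpy as np
import scipy.signal

from ndoa import NoiseSpec, StateSchedule, generate

schedule = StateSchedule([("awake", 40), ("moderate", 30), ("deep", 50),
                          ("awake", 30)])
noise = NoiseSpec(sqi_dropouts=[(75, 10)])
log = generate(schedule, noise, seed=7)

fs = log.recording.fs
for state, lo, hi in schedule.spans():
    seg = log.recording.samples[int((lo + 5) * fs):int((hi - 5) * fs)]
    f, p = scipy.signal.periodogram(seg, fs)
    slow = p[(f >= 0.5) & (f < 4)].sum()
    mid = p[(f >= 8) & (f < 30)].sum()
    print(f"{state:>9s} [{lo:3d},{hi:3d}) s  std {seg.std():5.1f} uV  "
          f"(8-30 Hz)/(0.5-4 Hz) power ratio {mid / slow:6.2f}")

ann = log.annotation_frame()
print("\nannotations around the SQI dropout (t=75..84):")
print(ann.iloc[73:87].to_string(index=False))
# A ratio > 1 marks awake-like broadband activity, < 1 deep-like slow waves;
# during the dropout the reference index is the invalid sentinel.
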