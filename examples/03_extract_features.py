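"""Extract the five features from awake-like and deep-like windows.

Entropies (SE, FE, PE) fall with anaesthetic depth (the EEG becomes more
regular); the Hurst range response and the wavelet-PSD eigenvector feature
grow with the slow high-voltage waves of deep anaesthesia."""

import numpy as np

from ndoa import StateSchedule, extract_features, generate, remove_outliers

print(f"{'state':>8s} {'SE':>7s} {'FE':>7s} {'PE':>7s} "
      f"{'HurstRR':>9s} {'PSDFea':>9s}")
for state in ("awake", "light", "moderate", "deep"):
    log = generate(StateSchedule([(state, 70)]), seed=17)
    rows = []
    for t in range(0, 60, 5):
        w = log.recording.samples[t * 128:(t + 10) * 128]
        fv = extract_features(remove_outliers(w))
        rows.append(fv.as_array())
    se, fe, pe, rr, psd = np.mean(rows, axis=0)
    print(f"{state:>8s} {se:7.3f} {fe:7.3f} {pe:7.3f} {rr:9.2f} {psd:9.1f}")
# Each row averages 12 overlapping 10 s windows of a single-state record.
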