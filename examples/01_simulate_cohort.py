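"""Simulate a small cue-reactivity cohort and inspect its ground truth.

Builds a cohort of smokers with two conditions (neutral / smoking guided
imagery), prints the generating dwell-time structure and the behavioural
table, and writes one recording to disk in the matrix + JSON format.
"""

from pathlib import Path

import numpy as np

import cuestate as cs

truth = cs.default_ground_truth(seed=1)
cohort = cs.generate_cohort(n_subjects=6, truth=truth, seed=1, n_trials=2, trial_s=30.0)

print("Ground-truth mean dwell times (ms), columns = neutral / smoking:")
for name, row in zip("ABCD", truth.dwell_mean_ms):
    print(f"  class {name}: {row[0]:6.1f}  {row[1]:6.1f}")
print(f"posterior alpha amplitude (uV): neutral {truth.alpha_amp[0]:.1f}, "
      f"smoking {truth.alpha_amp[1]:.1f}; snr {truth.snr}")

print("\nBehavioural table (first rows):")
print(cohort.behaviour[["subject", "condition", "craving", "vividness",
                        "years_smoking"]].head(6).to_string(index=False))

rec = cohort.recording("s00", "smoking")
print(f"\ns00/smoking recording: {rec.data.shape[0]} channels x "
      f"{rec.data.shape[1]} samples at {rec.srate:g} Hz, "
      f"cue onsets at {rec.onsets_s} s")
print("per-sample ground-truth labels retained:", np.bincount(rec.labels_true))

from cuestate import io as csio  # noqa: E402

Path("scratch").mkdir(exist_ok=True)
csio.write_recording("scratch/example_rec", rec)
print("wrote scratch/example_rec.f32 / .json")
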