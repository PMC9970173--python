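"""Preprocess one simulated block and measure posterior alpha power.

Runs the canonical chain (0.1-80 Hz filter, cue-locked epoching with
baseline correction, 1 s segmentation, +/-100 uV rejection, 250 Hz
resampling, 2-20 Hz filter, average reference) and compares the
posterior 8-12 Hz power between conditions for one subject.
"""

import cuestate as cs
from cuestate.preprocess import EEGRecording, posterior_alpha_power, preprocess_recording

truth = cs.default_ground_truth(seed=2)
cohort = cs.generate_cohort(n_subjects=3, truth=truth, seed=2, n_trials=2, trial_s=30.0)

for cond in ("neutral", "smoking"):
    sim = cohort.recording("s00", cond)
    rec = EEGRecording(sim.data, sim.srate, truth.montage.names, truth.montage)
    broad, ms = preprocess_recording(rec, sim.onsets_s, select=(1.0, 31.0))
    alpha = posterior_alpha_power(broad)
    print(f"{cond:8s}: {broad.n_epochs} clean 1 s epochs, "
          f"posterior alpha power {alpha.power:7.3f} uV^2 "
          f"(true amplitude {cohort.subjects[0].alpha_amp[int(cond == 'smoking')]:.2f} uV)")

print("\nA higher smoking-condition alpha power mirrors the generating truth:")
print("the cohort links each subject's alpha increase to its class-C dwell increase.")
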