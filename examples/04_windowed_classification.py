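"""Per-second-window decoding of a task pair from EEG, NIRS and fusion.

Simulates one subject performing mental rotation vs face imagery, extracts
620 EEG log band-power features and 219 NIRS mean-concentration features per
1 s window, and trains an L1-sparse linear SVM per window with repeated
stratified cross-validation, scoring held-out folds with Cohen's kappa.

The printed time courses show the study's core temporal signature: EEG
decodes from the first task second (oscillatory effects are instantaneous),
while NIRS only becomes informative once the delayed hemodynamic response
develops, peaking around 10 s.
"""

import numpy as np

import nirseeg as ns

paradigm = ns.ParadigmSpec(tasks=("ROT", "FACE"), reps_per_subsession=4,
                           n_subsessions=2, n_sessions=1)
montage = ns.default_montage()
config = ns.SimulationConfig(seed=11, cardiac_bpm=66.0)

schedule, sessions = ns.generate_subject(paradigm, montage, config, subject=0)
eeg, nirs = ns.subject_feature_sets(schedule, sessions, montage)
fused = ns.fuse_feature_sets(eeg, nirs)
print(f"features/window: EEG {eeg.n_features}, NIRS {nirs.n_features}, "
      f"fused {fused.n_features}; epochs: {eeg.n_epochs}")

windows = np.array([-3.0, 1.0, 5.0, 11.0])
scheme = ns.CVScheme(n_repeats=3, n_folds=5, seed=0)
print(f"\nmean held-out kappa ({scheme.n_estimates} estimates/window):")
print("window start   EEG    NIRS   fused")
results = {
    name: ns.run_windowed_cv(f, ("ROT", "FACE"), scheme, windows=windows)
    for name, f in (("EEG", eeg), ("NIRS", nirs), ("fused", fused))
}
for i, w in enumerate(windows):
    row = [results[m].perf["mean_kappa"].iloc[i] for m in ("EEG", "NIRS", "fused")]
    print(f"   {w:+5.0f} s   {row[0]:+.2f}   {row[1]:+.2f}   {row[2]:+.2f}")
print("\n(kappa 0 = chance, 0.4 = 70% balanced accuracy, 1 = perfect;"
      "\n the -3 s baseline window fluctuates around 0 -- with only 16 epochs"
      "\n a single CV estimate easily swings by +/-0.3)")
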