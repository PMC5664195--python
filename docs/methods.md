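# Methods

This note documents the models, conventions and numerical choices behind
`nirseeg`, and what its synthetic benchmark does and does not establish.

## Scope and shape

The package is a library: the importable API plus the narrative scripts in
`examples/` are the interface. Simulation, feature extraction,
classification and reporting are all plain functions over explicit data
containers (`TrialSchedule`, `EpochSet`, `HemoSeries`,
`WindowedFeatureMatrix`, …), so any stage can be run, replaced or probed in
isolation. No shell CLI is provided; the analysis is driven from Python.
Recordings are exchanged in a plain-text fixture format (TSV signals, JSON
montage/ground truth) written by `generate_dataset` and read by
`io.read_session`.

## Synthetic sessions

The generator produces multimodal recordings with the statistical structure
the analysis assumes — not biophysically realistic head signals. All
randomness derives from one seed via named child streams
(`_seeding.child_seed`), so a configuration reproduces byte-identical data.

**Trial schedule.** Within each subsession the task multiset (each task ×
repetitions) is randomly permuted; rests are uniform on [10, 15] s; 30 s
baselines flank each subsession; the cue occupies the 3 s before each task
onset. Defaults follow the 7-task, 4×4×3 design (336 trials/subject).

**EEG.** Per channel: 1/f Gaussian background (sd 1.0, arbitrary units)
plus one sinusoidal oscillator per band (θ, α_low, α_high, β_low, β_high)
with a seeded random frequency inside the band and random phase. Baseline
amplitudes (2.0, 2.5, 2.5, 1.2, 0.8) put clear alpha dominance over a small
beta floor. A task effect e for (task, region, band) scales the affected
oscillators' amplitude by √(1+e) during task execution with 0.5 s cosine
ramps, so band-limited *variance* changes by the fraction e (negative =
ERD). The default effect table encodes the canonical qualitative patterns
(occipital α/β suppression for rotation, left-temporal α for word
generation, left-central μ/β for motor imagery, frontal θ enhancement for
subtraction, weaker imagery effects) at magnitudes 0.25–0.5; the literature
does not quantify these effect sizes, so the magnitudes are free parameters
that give task pairs distinguishable structure without claiming quantitative
fidelity.

**NIRS.** Per trial, a hemodynamic kernel — a unit-peak gamma wave minus a
0.15-weighted wider gamma undershoot, parameterized by onset delay (2 s) and
time-to-peak measured from task onset (11 s) — is scaled by the (task,
region, chromophore) amplitude map (defaults ~0.5–0.8 µmol/L HbO, −0.25
HbR) and summed into per-channel Δ[HbO]/Δ[HbR] series; short channels
receive no cortical response. Concentrations pass through the forward
Beer–Lambert model to optical densities, to which are added:

* a common cardiac sinusoid at the subject's heart rate (drawn from 45–100
  BPM unless fixed), amplitude 0.005 OD on long channels and ×3 on the four
  short channels (which makes the short-channel QC meaningful);
* per-channel 1/f baseline wander, sd 0.01 OD. Continuous-wave NIRS
  baselines are dominated by slow instrumental and superficial-physiology
  drift, several times the white-noise floor in the analysis band. This
  component matters beyond realism: the 0.01 Hz zero-phase high-pass in the
  analysis redistributes a fraction of each trial's response integral across
  its own epoch, and on drift-free synthetic data that residue is a
  class-correlated offset detectable even before the response onset — a
  decoding artifact real recordings do not exhibit because drift swamps it;
* white noise, sd 0.003 OD.

Intensities are `baseline(λ)·exp(−OD)`, strictly positive. Epoch rejection
and movement artifacts are not simulated; Mayer waves and respiration are
out of scope.

## EEG pipeline

Preprocessing references to Cz, resamples 512→256 Hz (polyphase),
band-passes 0.5–100 Hz (4th-order Butterworth, forward–backward), applies a
58–62 Hz band-stop in place of a notch, and re-references to the channel
average (on average-free synthetic data the Cz step is a no-op; both are
exposed for real recordings). Epochs cover [−5, 20) s with the −300…0 ms
mean subtracted per channel. Trials overrunning the recording are dropped
with a warning. ICA cleaning and visual rejection are intentionally absent;
an external boolean epoch mask can stand in for them.

ERD/ERS uses the intertrial variance method: band-pass the epochs, subtract
the across-trial mean at each time point (removing the evoked component),
compute the across-trial variance IV(t) per channel, and report
100·(⟨IV⟩_analysis − ⟨IV⟩_reference)/⟨IV⟩_reference with reference −2…0 s
and analysis 0.5…2 s. At least two epochs are required; the quantity is
bounded below by −100%.

Band powers use a single unwindowed DFT per 1 s window (256 samples, 1 Hz
resolution); band power sums squared-magnitude bins whose centre lies in
[lo, hi). Eight bands are emitted per channel — the seven named bands plus
α_total (8–12 Hz) — together with two ratios computed on linear powers
(α_total/β_total and θ/β_total, with β_total = 12–30 Hz computed internally
but not emitted). This is the only integer-consistent reading of the
620 = 62 × 10 feature layout. All ten values are natural-log transformed
(a single log; the log base only shifts the scale), with a 1e−12 floor for
degenerate all-zero windows.

## NIRS pipeline

Optical density is the natural-log convention OD = −ln(I/Ī) with Ī the
channel-wavelength mean over the recording; any non-positive sample is an
error naming the channel.

**Channel QC.** The OD (760 nm by default) is band-passed 0.8–1.2 Hz
(3rd-order zero-phase Butterworth). Per trial epoch, each long channel is
Pearson-correlated with each same-side short channel; midline channels
would use all four. Because narrow band-passed samples are strongly
serially dependent, the i.i.d. correlation p-value is grossly
anticonservative; p-values therefore use a Bartlett-type effective sample
size, n_eff = n / (1 + 2·Σ_k (1 − k/n)·ρ_x(k)·ρ_y(k)), clipped to [5, n].
Without this correction, independent noise channels are "significantly"
correlated with the short channels almost always and the rejection rule is
vacuous; with it the null retention rate sits at the nominal α (verified at
5.3% over seeded runs). Per channel the smaller of the two same-side
p-values is kept per epoch and the epochs are aggregated with Fisher's
method; a channel is retained iff the aggregate p < 0.05. Short channels
are always retained; zero-variance epochs are skipped, and a channel with
no usable epoch is rejected. Note the band covers 48–72 BPM: a pulse
outside it is undetectable by construction (real pulse waveforms carry
harmonics and rate variability that widen this, a pure simulated tone does
not).

**MBLL.** OD is band-passed 0.01–0.30 Hz (3rd-order zero-phase) and the
2×2 system ΔOD(λ) = [ε_HbO(λ)Δ[HbO] + ε_HbR(λ)Δ[HbR]]·d·DPF(λ) is solved
per sample and channel. Defaults: ε from a standard extinction table at
760/850 nm expressed in L·µmol⁻¹·cm⁻¹ under the natural-log convention
(760: 5.86e−4 / 1.5485e−3; 850: 1.058e−3 / 6.9132e−4 for HbO/HbR),
DPF = 6.0 at both wavelengths, d = 3 cm; all configurable, and a singular
coefficient matrix is a configuration error. Δ[HbT] = Δ[HbO] + Δ[HbR] by
definition. The band-pass can be disabled (`hp_lp=None`) for exact
forward/inverse verification, since any band-pass perturbs the slow
response waveform itself.

13 regional channels are appended as means over each region's *retained*
members (an all-rejected region yields a zero, rejected regional channel).
Features — the mean concentration per (channel, chromophore) in each 1 s
window — are zeroed for rejected channels only after regional averaging, so
the 219-feature layout is stable while bad data never propagates.
Response maps average baseline-normalized epochs (mean of −5…0 s
subtracted) over trials and the 10–15 s window.

## Classification

Per window, the decoder is scikit-learn's liblinear L1-penalized linear SVM
(`LinearSVC(penalty="l1", loss="squared_hinge", dual=False)`, tol 1e−4,
max 5000 iterations with convergence logged). The L1-regularized linear-SVM
family fixes the estimator; among its dialects the squared-hinge coordinate
descent solver is the mature, exactly-sparse implementation, and the
properties the analysis relies on — embedded feature selection, the C/n
scaling, the zero-feature fallback — are dialect-independent. The intercept
is effectively unpenalized via `intercept_scaling=100` (with Z-scored
features it is near zero anyway). Effective C is `2.0 / n_train` with the
actual training-partition size, reproducing 0.023 for 10-fold splits of 96
epochs. Features are Z-normalized with training-fold statistics only
(zero-variance features get unit sd). A model whose every |w| ≤ 1e−8
predicts the majority training class; its held-out κ is computed normally
(≈ 0).

Cross-validation is repeated stratified k-fold (default 10×10 = 100
estimates per window), reshuffled between repetitions, each repetition
seeded from the scheme seed via named child streams. κ is computed per
held-out fold from its 2×2 confusion table, with p_e = 1 defined as κ = 0;
single-class training folds are skipped with a warning and fewer than half
the expected estimates is an error. A final model refit on all epochs
supplies the weights used for importance. Windows are indexed by their
start second relative to onset; baseline windows are classifiable, but peak
extraction uses only the 15 task windows (0–14 s start), ties resolved to
the earliest window. The fusion gain Δκ is evaluated at the NIRS peak
window w* per subject and pair.

## Group statistics

Pair ranking: one-sample two-tailed t per pair against κ₀ = 0.4, ranked by
descending t; a zero-variance κ vector degenerates to t = ±∞ by mean side
(logged, not an error). Fusion: paired two-tailed t per pair, fused vs EEG
peaks. Both families use the hand-implemented Holm–Bonferroni step-down
(cross-checked against statsmodels), with significance tiers ∗/∗∗/∗∗∗ at
adjusted p < 0.05/0.01/0.001. Importance is the mean |w| across models in a
shared feature space; channel and subtype aggregates are means over member
features (not sums), so channels contributing 10 EEG features remain
comparable to channels contributing 3 NIRS features; ranks break ties by
stable feature order.

## Desk-scale benchmark sizes

The quantitative self-checks in `tests/test_acceptance.py` use: a 4-subject,
two-task (rotation vs face imagery) cohort with 4 repetitions × 4
subsessions × 2 sessions (64 epochs per pair) and 5×5 CV for the
temporal-structure analogue; 1 session (32 epochs) for the
complementary-information fusion analogue (no EEG effects, full-strength
hemodynamics); 200 seeded runs for QC operating characteristics (heart
rates drawn within the 0.8–1.2 Hz QC band); 8 label permutations for the
permutation null; and 1000 replicates for the family-wise-error
calibration. For the temporal-structure analogue the hemodynamic amplitudes
are scaled to 0.4× the qualitative defaults so that NIRS peak decodability
lands in the satisfactory-to-high range (peak κ ≈ 0.74–0.90 at 10–14 s)
instead of saturating at κ = 1, which keeps peak-time estimates meaningful.

Two estimator choices deserve note. First, the permutation null is
summarized by the mean window-κ across independent permutations: a single
fixed permutation has a null spread of order 1/√n_epochs that repeated CV
cannot reduce (every split shares the permutation's chance alignment with
the class structure), so individual permutations legitimately reach |κ| ≈
0.3–0.5 at n = 64 on nearly noiseless features while the permutation mean
stays within ±0.1 of zero. Second, "noiseless end-to-end" concentration
recovery is verified with the 0.01–0.30 Hz filter disabled, because the
filter reshapes the slow response waveform by far more than the 1e−6
comparison tolerance; the filter path is exercised separately by the
decoding analogues.

## What passing does and does not show

The synthetic benchmark establishes that every stage implements its
contract: timing and counts, spectral effect recovery within sampling
tolerance, exact κ and MBLL algebra, calibrated QC, the EEG-early/NIRS-late
temporal dissociation, a positive fusion gain when modalities carry
complementary information, and honest null behaviour. It does **not**
establish performance on real recordings: the generator omits eye/muscle
artifacts, bad channels, systemic physiology (Mayer waves, respiration),
inter-subject anatomical variability, and non-stationarities, and its
effect sizes are qualitative choices. Results on real data additionally
depend on the artifact-cleaning steps (ICA, visual rejection) that are
deliberately out of scope here.

Known limitations: the cardiac model is a pure tone, so QC sensitivity is
only defined for rates inside the 0.8–1.2 Hz band; zero-phase filtering
smears response energy symmetrically in time, so early-window NIRS κ is an
upper bound on causal decodability; and liblinear's exact sparsity pattern
near the selection threshold can differ from other L1-SVM solvers by a
feature or two at matched C.
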