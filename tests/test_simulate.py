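"""Generator contracts: determinism, bookkeeping, and recovery of the
configured effects by independent spectral/forward-model oracles."""

import math

import numpy as np
import pytest
from scipy import signal as sps_signal

import nirseeg as ns
from nirseeg.exceptions import ConfigurationError
from nirseeg.montage import EEG_REGIONS


def _tiny_schedule(tasks=("ROT",), reps=2, seed=4):
    par = ns.ParadigmSpec(tasks=tasks, reps_per_subsession=reps, n_subsessions=1, n_sessions=1)
    return ns.generate_schedule(par, seed)


def test_eeg_row_count_and_determinism(montage):
    sched = _tiny_schedule()
    cfg = ns.SimulationConfig(seed=1, cardiac_bpm=60.0)
    a = ns.simulate_eeg(sched, montage, cfg, session=0)
    b = ns.simulate_eeg(sched, montage, cfg, session=0)
    assert a.shape == (math.ceil(sched.session_duration(0) * cfg.eeg_rate), 62)
    np.testing.assert_array_equal(a, b)


def test_nirs_intensities_positive_and_deterministic(montage):
    sched = _tiny_schedule()
    cfg = ns.SimulationConfig(seed=1, cardiac_bpm=60.0)
    a = ns.simulate_nirs(sched, montage, cfg, session=0)
    b = ns.simulate_nirs(sched, montage, cfg, session=0)
    assert a.shape == (math.ceil(sched.session_duration(0) * cfg.nirs_rate), 60, 2)
    assert np.all(a > 0)
    np.testing.assert_array_equal(a, b)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        ns.SimulationConfig(effect_table={("ROT", "occipital", "alpha_high"): -1.0})
    with pytest.raises(ConfigurationError):
        ns.SimulationConfig(effect_table={("ROT", "occipital", "nonsense_band"): -0.5})
    with pytest.raises(ConfigurationError):
        ns.SimulationConfig(baseline_intensity={760: 0.0, 850: 1.0})
    with pytest.raises(ConfigurationError):
        ns.SimulationConfig(cardiac_bpm=200.0)


def test_erd_effect_scales_band_variance(erd_sim, montage):
    """A -0.5 high-alpha effect halves band-limited variance during the task
    (independent band-filter oracle on the raw 512 Hz signal)."""
    raw = erd_sim["raw"]
    cfg = erd_sim["config"]
    trials = erd_sim["schedule"].absolute_trials(0)
    sos = sps_signal.butter(4, [10 / 256.0, 12 / 256.0], btype="bandpass", output="sos")
    t = np.arange(raw.shape[0]) / cfg.eeg_rate
    task_mask = np.zeros(raw.shape[0], bool)
    rest_mask = np.zeros(raw.shape[0], bool)
    for onset in trials["onset_abs_s"]:
        task_mask |= (t >= onset + 1.0) & (t < onset + 14.0)  # clear of the ramps
        rest_mask |= (t >= onset - 8.0) & (t < onset - 3.0)   # pre-cue rest

    effect = cfg.effect_table[("ROT", "occipital", "alpha_high")]
    for ch, inside in (("O2", True), ("Cz", False)):
        x = sps_signal.sosfiltfilt(sos, raw[:, montage.eeg_channels.index(ch)])
        ratio = x[task_mask].var() / x[rest_mask].var()
        expected = 1.0 + effect if inside else 1.0
        assert abs(ratio - expected) < 0.15 * expected, (ch, ratio)


def test_cardiac_spectral_peak(montage):
    """66 BPM cardiac -> 1.1 Hz peak in the band-passed short-channel OD."""
    sched = _tiny_schedule(reps=4)
    cfg = ns.SimulationConfig(seed=2, cardiac_bpm=66.0)
    raw = ns.simulate_nirs(sched, montage, cfg, session=0)
    od = ns.intensities_to_od(raw, montage.nirs_channels, cfg.nirs_rate)
    i = montage.nirs_channels.index("S15-D1")
    nyq = cfg.nirs_rate / 2
    sos = sps_signal.butter(3, [0.8 / nyq, 1.2 / nyq], btype="bandpass", output="sos")
    x = sps_signal.sosfiltfilt(sos, od.data[:, i, 0])
    f, p = sps_signal.periodogram(x, fs=cfg.nirs_rate)
    assert abs(f[np.argmax(p)] - 1.1) <= f[1] - f[0]


def test_null_hemodynamics_mean_zero(montage):
    """Zero response amplitudes -> task-window mean HbO within 3 SE of 0."""
    sched = _tiny_schedule(reps=6)
    cfg = ns.SimulationConfig(seed=8, cardiac_bpm=66.0, hrf=ns.HRFSpec(amplitudes={}))
    raw = ns.simulate_nirs(sched, montage, cfg, session=0)
    od = ns.intensities_to_od(raw, montage.nirs_channels, cfg.nirs_rate)
    hemo = ns.od_to_hemoglobin(od)
    t = np.arange(hemo.data.shape[0]) / hemo.rate
    # one value per trial (channel-averaged): trials are the independent units
    trial_means = []
    for onset in sched.absolute_trials(0)["onset_abs_s"]:
        m = (t >= onset) & (t < onset + 15.0)
        trial_means.append(hemo.data[m, :, 0].mean())
    trial_means = np.asarray(trial_means)
    se = trial_means.std(ddof=1) / np.sqrt(trial_means.size)
    assert abs(trial_means.mean()) < 3 * se
    assert abs(trial_means.mean()) < 0.05  # far below typical response amplitudes


def test_time_to_peak_recovered(montage):
    """Configured 8 s time-to-peak -> recovered mean HbO peaks in 6-12 s."""
    sched = _tiny_schedule(reps=6)
    cfg = ns.SimulationConfig(
        seed=5, cardiac_bpm=66.0, nirs_noise_sd=0.0, nirs_drift_sd=0.0,
        cardiac_od_amplitude=0.0, hrf=ns.HRFSpec(time_to_peak_s=8.0),
    )
    raw, true_conc, _ = ns.simulate_nirs(sched, montage, cfg, session=0, return_truth=True)
    od = ns.intensities_to_od(raw, montage.nirs_channels, cfg.nirs_rate)
    hemo = ns.od_to_hemoglobin(od, hp_lp=None)
    ch = montage.region_map["centrofrontal_left"][0]
    i = montage.nirs_channels.index(ch)
    t = np.arange(hemo.data.shape[0]) / hemo.rate
    rel = np.arange(-5.0, 20.0, 1.0 / cfg.nirs_rate)
    traces = []
    for onset in sched.absolute_trials(0)["onset_abs_s"]:
        idx = np.searchsorted(t, onset + rel)
        tr = hemo.data[idx, i, 0]
        traces.append(tr - tr[rel < 0].mean())
    mean_trace = np.mean(traces, axis=0)
    t_peak = rel[np.argmax(mean_trace)]
    assert 6.0 <= t_peak <= 12.0


def test_hrf_kernel_shape():
    spec = ns.HRFSpec(onset_delay_s=2.0, time_to_peak_s=11.0)
    t = np.linspace(-5, 1e4, 5000)
    h = ns.hrf_kernel(t, spec)
    assert np.all(np.isfinite(h))
    assert np.all(h[t <= 2.0] == 0)
    assert h.max() == pytest.approx(1.0)
    assert abs(t[np.argmax(h)] - 11.0) < 2.0  # undershoot shifts the peak slightly


def test_generate_dataset_layout_and_determinism(tmp_path, montage):
    par = ns.ParadigmSpec(
        tasks=("ROT",), reps_per_subsession=1, n_subsessions=1, n_sessions=1,
        cue_s=1.0, task_s=2.0, rest_min_s=2.0, rest_max_s=3.0, baseline_s=5.0,
    )
    cfg = ns.SimulationConfig(seed=3, cardiac_bpm=60.0)
    paths_a = ns.generate_dataset(par, montage, cfg, 2, tmp_path / "a")
    paths_b = ns.generate_dataset(par, montage, cfg, 2, tmp_path / "b")
    assert len(paths_a) == 2  # one session per subject here
    assert sorted(p.parent.name for p in paths_a) == ["subject-01", "subject-02"]
    for pa, pb in zip(paths_a, paths_b):
        for name in ("schedule.tsv", "eeg.tsv", "nirs.tsv", "montage.json", "ground_truth.json"):
            assert (pa / name).read_bytes() == (pb / name).read_bytes(), name
    with pytest.raises(ConfigurationError):
        ns.generate_dataset(par, montage, cfg, 0, tmp_path / "c")


def test_fixture_roundtrip(tmp_path, montage):
    from nirseeg import io

    par = ns.ParadigmSpec(
        tasks=("ROT",), reps_per_subsession=1, n_subsessions=1, n_sessions=1,
        cue_s=1.0, task_s=2.0, rest_min_s=2.0, rest_max_s=3.0, baseline_s=5.0,
    )
    cfg = ns.SimulationConfig(seed=3, cardiac_bpm=60.0)
    schedule, sessions = ns.generate_subject(par, montage, cfg, 0)
    path = io.write_session(tmp_path, 0, sessions[0], montage, schedule)
    loaded, montage2 = io.read_session(path)
    assert montage2.nirs_channels == montage.nirs_channels
    np.testing.assert_allclose(loaded.eeg, sessions[0].eeg, rtol=1e-6, atol=1e-8)
    np.testing.assert_allclose(loaded.nirs, sessions[0].nirs, rtol=1e-6)
    assert loaded.ground_truth.seed == cfg.seed
    assert loaded.schedule.trials["task"].tolist() == \
        schedule.session_view(0).trials["task"].tolist()


def test_eeg_regions_used_by_default_effects(montage):
    for task, region, _ in ns.default_effect_table():
        assert region in EEG_REGIONS
        assert task in ns.TASKS
    for task, region, chromo in ns.default_hemo_amplitudes():
        assert region in montage.region_map
        assert chromo in ("HbO", "HbR")
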