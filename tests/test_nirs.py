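"""NIRS pipeline: OD conversion, MBLL inversion, QC, regions, features."""

import numpy as np
import pandas as pd
import pytest

import nirseeg as ns
from nirseeg.exceptions import ConfigurationError
from nirseeg.nirs import CHROMOPHORES, HemoSeries, ODSeries

CH3 = ("S1-D1", "S1-D2", "S1-D3")


# -------------------------------------------------------------- optical density

def test_od_of_constant_channel_is_zero():
    od = ns.intensities_to_od(np.full((50, 2, 2), 4.2), ("a", "b"), 4.46)
    np.testing.assert_allclose(od.data, 0.0, atol=1e-15)


def test_od_value_convention():
    x = np.ones((10, 1, 2))
    x[3, 0, 0] = 0.1  # one sample at a tenth of ~unit mean
    od = ns.intensities_to_od(x, ("a",), 4.46)
    mean = x[:, 0, 0].mean()
    assert od.data[3, 0, 0] == pytest.approx(np.log(mean / 0.1))


def test_od_scale_invariance(rng):
    x = np.exp(rng.standard_normal((100, 2, 2)) * 0.05)
    od1 = ns.intensities_to_od(x, ("a", "b"), 4.46)
    od2 = ns.intensities_to_od(2.7 * x, ("a", "b"), 4.46)
    np.testing.assert_allclose(od1.data, od2.data, atol=1e-12)


def test_od_rejects_nonpositive_sample():
    x = np.ones((10, 2, 2))
    x[5, 1, 0] = -1.0
    with pytest.raises(ConfigurationError, match="S1-D2"):
        ns.intensities_to_od(x, ("S1-D1", "S1-D2"), 4.46)


# ----------------------------------------------------------------------- MBLL

def test_mbll_roundtrip_exact():
    coeffs = ns.MBLLCoefficients()
    true = np.array([1.0, -0.5])  # micromol/L
    od_vec = coeffs.matrix() @ true
    od = ODSeries(np.tile(od_vec, (40, 3, 1)), CH3, 4.46)
    hemo = ns.od_to_hemoglobin(od, coeffs, hp_lp=None)
    expected = np.broadcast_to(true, hemo.data[..., :2].shape)
    np.testing.assert_allclose(hemo.data[..., :2], expected, atol=1e-8)


def test_mbll_zero_and_hbt_identity(rng):
    od = ODSeries(np.zeros((20, 3, 2)), CH3, 4.46)
    hemo = ns.od_to_hemoglobin(od, hp_lp=None)
    np.testing.assert_allclose(hemo.data, 0.0, atol=1e-15)
    od2 = ODSeries(rng.standard_normal((200, 3, 2)) * 0.01, CH3, 4.46)
    hemo2 = ns.od_to_hemoglobin(od2)
    np.testing.assert_allclose(
        hemo2.data[..., 2], hemo2.data[..., 0] + hemo2.data[..., 1], atol=1e-12
    )


def test_mbll_linearity(rng):
    od = ODSeries(rng.standard_normal((50, 3, 2)) * 0.01, CH3, 4.46)
    od2 = ODSeries(2.0 * od.data, CH3, 4.46)
    h1 = ns.od_to_hemoglobin(od, hp_lp=None)
    h2 = ns.od_to_hemoglobin(od2, hp_lp=None)
    np.testing.assert_allclose(h2.data, 2.0 * h1.data, rtol=1e-10)


def test_singular_coefficients_rejected():
    coeffs = ns.MBLLCoefficients(
        extinction={760: {"HbO": 1.0, "HbR": 1.0}, 850: {"HbO": 1.0, "HbR": 1.0}}
    )
    with pytest.raises(ConfigurationError):
        coeffs.matrix()


# ------------------------------------------------------------------------- QC

def test_short_channels_always_retained(small_subject, montage):
    sess = small_subject["sessions"][0]
    od = ns.intensities_to_od(sess.nirs, montage.nirs_channels, sess.nirs_rate)
    onsets = small_subject["schedule"].absolute_trials(0)["onset_abs_s"].to_numpy()
    qc = ns.qc_cardiac_channels(od, montage, onsets)
    t = qc.table.set_index("channel")
    for sc in montage.short_channels:
        assert t.loc[sc, "retained"]
        assert t.loc[sc, "aggregate_p"] == 0.0
    # cardiac-bearing long channels correlate with the shorts
    assert t.loc[list(montage.long_channels), "retained"].all()


def test_cardiac_free_channel_rejected(montage):
    par = ns.ParadigmSpec(tasks=("ROT",), reps_per_subsession=8,
                          n_subsessions=1, n_sessions=1)
    sched = ns.generate_schedule(par, 6)
    free = ("S1-D1", "S9-D15")
    rejected = 0
    for seed in range(5):
        cfg = ns.SimulationConfig(seed=seed, cardiac_bpm=70.0,
                                  cardiac_free_channels=free,
                                  hrf=ns.HRFSpec(amplitudes={}))
        raw = ns.simulate_nirs(sched, montage, cfg, session=0)
        od = ns.intensities_to_od(raw, montage.nirs_channels, cfg.nirs_rate)
        qc = ns.qc_cardiac_channels(od, montage,
                                    sched.absolute_trials(0)["onset_abs_s"].to_numpy())
        t = qc.table.set_index("channel")
        rejected += int((~t.loc[list(free), "retained"]).sum())
    assert rejected >= 8  # noise-only channels are rejected in the vast majority of runs


def test_qc_zero_variance_channel_not_retained(montage):
    """A dead (constant-intensity) channel yields no usable epochs."""
    par = ns.ParadigmSpec(tasks=("ROT",), reps_per_subsession=3,
                          n_subsessions=1, n_sessions=1)
    sched = ns.generate_schedule(par, 6)
    cfg = ns.SimulationConfig(seed=1, cardiac_bpm=70.0)
    raw = ns.simulate_nirs(sched, montage, cfg, session=0)
    raw[:, 0, :] = 1.0  # S1-D1 dead
    od = ns.intensities_to_od(raw, montage.nirs_channels, cfg.nirs_rate)
    qc = ns.qc_cardiac_channels(od, montage,
                                sched.absolute_trials(0)["onset_abs_s"].to_numpy())
    row = qc.table.set_index("channel").loc["S1-D1"]
    assert not row["retained"]


# -------------------------------------------------------------------- regions

def _hemo(data, channels, retained=None):
    retained = retained if retained is not None else np.ones(len(channels), bool)
    return HemoSeries(data, channels, 4.46, retained)


def test_regional_channels_count(small_subject, montage):
    sess = small_subject["sessions"][0]
    od = ns.intensities_to_od(sess.nirs, montage.nirs_channels, sess.nirs_rate)
    hemo = ns.od_to_hemoglobin(od)
    out = ns.add_regional_channels(hemo, montage.region_map)
    assert len(out.channels) == 73
    assert out.data.shape[1] == 73
    np.testing.assert_allclose(out.data[..., 2], out.data[..., 0] + out.data[..., 1],
                               atol=1e-12)


def test_regional_average_semantics(rng):
    data = rng.standard_normal((30, 2, 3))
    data[:, 1, :] = data[:, 0, :]  # identical members
    hemo = _hemo(data, ("S1-D1", "S1-D2"))
    out = ns.add_regional_channels(hemo, {"r": ("S1-D1", "S1-D2")})
    np.testing.assert_allclose(out.data[:, 2], data[:, 0])
    single = ns.add_regional_channels(hemo, {"r": ("S1-D2",)})
    np.testing.assert_allclose(single.data[:, 2], data[:, 1])


def test_regional_excludes_rejected_members(rng):
    data = rng.standard_normal((30, 2, 3))
    hemo = _hemo(data, ("S1-D1", "S1-D2"), retained=np.array([True, False]))
    out = ns.add_regional_channels(hemo, {"r": ("S1-D1", "S1-D2")})
    np.testing.assert_allclose(out.data[:, 2], data[:, 0])
    all_rej = _hemo(data, ("S1-D1", "S1-D2"), retained=np.array([False, False]))
    out2 = ns.add_regional_channels(all_rej, {"r": ("S1-D1", "S1-D2")})
    assert not out2.retained[-1]
    np.testing.assert_allclose(out2.data[:, 2], 0.0)
    with pytest.raises(ConfigurationError):
        ns.add_regional_channels(hemo, {"r": ("S9-D9",)})


# ------------------------------------------------------------------- features

def test_nirs_feature_count(small_features):
    _, nirs = small_features
    assert nirs.n_features == 219
    assert nirs.n_windows == 25
    assert (nirs.meta["modality"] == "NIRS").all()
    assert set(nirs.meta["subtype"]) == set(CHROMOPHORES)
    assert nirs.meta["channel"].nunique() == 73


def test_rejected_channel_features_zeroed(rng):
    data = rng.standard_normal((500, 2, 3))
    hemo = _hemo(data, ("S1-D1", "S1-D2"), retained=np.array([True, False]))
    onsets = np.array([30.0, 60.0])
    feats = ns.extract_nirs_features(hemo, onsets, np.array(["ROT", "FACE"]))
    rej = feats.meta["channel"] == "S1-D2"
    assert np.all(feats.values[:, :, rej.to_numpy()] == 0.0)
    assert not np.all(feats.values[:, :, (~rej).to_numpy()] == 0.0)


def test_constant_series_gives_constant_features():
    data = np.full((500, 1, 3), 2.5)
    feats = ns.extract_nirs_features(_hemo(data, ("S1-D1",)),
                                     np.array([30.0]), np.array(["ROT"]))
    np.testing.assert_allclose(feats.values, 2.5)
    np.testing.assert_allclose(feats.window_starts, np.arange(-5.0, 20.0))


# --------------------------------------------------------------- response map

def test_response_map_trivials(rng):
    zeros = _hemo(np.zeros((600, 2, 3)), ("S1-D1", "S1-D2"))
    onsets = np.array([40.0, 80.0])
    m = ns.average_response_map(zeros, onsets, np.array(["ROT", "ROT"]), "ROT")
    np.testing.assert_allclose(m.to_numpy(), 0.0)
    data = rng.standard_normal((600, 2, 3))
    h1 = _hemo(data, ("S1-D1", "S1-D2"))
    h2 = _hemo(data + 7.0, ("S1-D1", "S1-D2"))  # constant offset
    m1 = ns.average_response_map(h1, onsets, np.array(["ROT", "ROT"]), "ROT")
    m2 = ns.average_response_map(h2, onsets, np.array(["ROT", "ROT"]), "ROT")
    np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-10)
    with pytest.raises(ConfigurationError):
        ns.average_response_map(h1, onsets, np.array(["ROT", "ROT"]), "MI")


def test_simulated_response_positive_in_target_region(small_subject, montage):
    """Mental rotation drives positive HbO in its configured frontal region."""
    sess = small_subject["sessions"][0]
    od = ns.intensities_to_od(sess.nirs, montage.nirs_channels, sess.nirs_rate)
    hemo = ns.od_to_hemoglobin(od)
    trials = small_subject["schedule"].absolute_trials(0)
    m = ns.average_response_map(
        hemo, trials["onset_abs_s"].to_numpy(), trials["task"].to_numpy(), "ROT"
    )
    members = montage.region_map["centrofrontal_left"]
    assert m.loc[list(members), "HbO"].mean() > 0.1
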