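"""Kappa, the sparse linear classifier, and windowed cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

import nirseeg as ns
from nirseeg.classify import confusion_2x2
from nirseeg.exceptions import ConfigurationError
from nirseeg.features import WindowedFeatureMatrix


def _table_to_labels(c):
    """Expand a 2x2 count table into rater label vectors."""
    (tp, fn), (fp, tn) = c
    y_true = [1] * (tp + fn) + [-1] * (fp + tn)
    y_pred = [1] * tp + [-1] * fn + [1] * fp + [-1] * tn
    return np.array(y_true), np.array(y_pred)


# ---------------------------------------------------------------------- kappa

@pytest.mark.parametrize(
    "table,expected",
    [
        ([[48, 0], [0, 48]], 1.0),
        ([[35, 15], [15, 35]], 0.4),
        ([[30, 18], [10, 38]], (0.70833333 - 0.5) / 0.5),
    ],
)
def test_kappa_known_values(table, expected):
    assert ns.cohens_kappa(table) == pytest.approx(expected, abs=1e-5)


def test_kappa_degenerate_and_errors():
    assert ns.cohens_kappa([[7, 0], [0, 0]]) == 0.0  # chance agreement is total
    with pytest.raises(ConfigurationError):
        ns.cohens_kappa([[1, -2], [0, 3]])
    with pytest.raises(ConfigurationError):
        ns.cohens_kappa([[0, 0], [0, 0]])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.tuples(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)))
def test_kappa_matches_sklearn(counts):
    tp, fn, fp, tn = counts
    if tp + fn + fp + tn == 0:
        return
    table = [[tp, fn], [fp, tn]]
    y_true, y_pred = _table_to_labels(table)
    ours = ns.cohens_kappa(table)
    theirs = cohen_kappa_score(y_true, y_pred)
    if np.isnan(theirs):  # sklearn's NaN convention for chance-saturated tables
        assert ours == 0.0
    else:
        assert ours == pytest.approx(theirs, abs=1e-12)


def test_balanced_kappa_accuracy_mapping():
    # balanced table: kappa = 2*accuracy - 1 exactly
    for correct in range(0, 41, 5):
        table = [[correct, 40 - correct], [40 - correct, correct]]
        acc = 2 * correct / 80
        assert ns.cohens_kappa(table) == pytest.approx(2 * acc - 1.0)


def test_accuracy_equivalences():
    assert ns.kappa_to_accuracy(0.4) == pytest.approx(70.0)
    assert ns.kappa_to_accuracy(0.0) == pytest.approx(50.0)
    assert ns.kappa_to_accuracy(1.0) == pytest.approx(100.0)
    assert ns.delta_kappa_to_accuracy_points(0.03) == pytest.approx(1.5)
    assert ns.delta_kappa_to_accuracy_points(0.20) == pytest.approx(10.0)
    with pytest.raises(ConfigurationError):
        ns.kappa_to_accuracy(1.5)


# ------------------------------------------------------------------- training

def test_effective_c_scaling():
    params = ns.TrainingParams()
    assert round(ns.effective_c(params, 86), 3) == 0.023
    assert ns.effective_c(params, 10) == pytest.approx(0.2)
    with pytest.raises(ConfigurationError):
        ns.effective_c(params, 0)


def test_penalty_dominated_limit_predicts_majority(rng):
    X = rng.standard_normal((40, 10))
    y = np.array([1] * 25 + [-1] * 15)
    model = ns.train_sparse_linear(X, y, ns.TrainingParams(c_base=1e-6 * 40))
    assert model.n_selected == 0
    assert np.all(model.predict(rng.standard_normal((7, 10))) == 1)


def test_separable_toy_selects_informative_feature(rng):
    n = 40
    y = np.array([1] * (n // 2) + [-1] * (n // 2))
    X = np.column_stack([y * 2.0 + rng.normal(0, 0.05, n), rng.standard_normal(n)])
    model = ns.train_sparse_linear(X, y)
    assert abs(model.weights[0]) > 1e-3
    assert abs(model.weights[1]) <= 1e-6
    kappa = ns.cohens_kappa(confusion_2x2(y, model.predict(X)))
    assert kappa == 1.0


def test_training_normalization_from_training_data_only(rng):
    X = rng.standard_normal((30, 5)) * 4.0 + 2.0
    y = np.array([1, -1] * 15)
    model = ns.train_sparse_linear(X, y)
    np.testing.assert_allclose(model.mean, X.mean(axis=0), atol=1e-12)
    np.testing.assert_allclose(model.sd, X.std(axis=0), atol=1e-12)
    z = (X - model.mean) / model.sd
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)


def test_single_class_rejected(rng):
    with pytest.raises(ConfigurationError):
        ns.train_sparse_linear(rng.standard_normal((10, 3)), np.ones(10))


def test_selected_count_nondecreasing_in_c(rng):
    """The regularization path adds features as C grows (solver-tolerance
    violations of at most one feature allowed)."""
    for seed in range(5):
        r = np.random.default_rng(seed)
        n = 60
        y = np.array([1, -1] * (n // 2))
        X = r.standard_normal((n, 30))
        X[:, :6] += y[:, None] * r.uniform(0.2, 0.8, 6)
        counts = []
        for c_base in (0.05, 0.2, 1.0, 5.0, 25.0):
            model = ns.train_sparse_linear(X, y, ns.TrainingParams(c_base=c_base * n))
            counts.append(model.n_selected)
        diffs = np.diff(counts)
        assert np.all(diffs >= -1), counts


# ---------------------------------------------------------------- windowed CV

def _toy_features(rng, n_epochs=96, n_windows=2, n_features=6, effect=1.5):
    labels = np.array(["A", "B"] * (n_epochs // 2))
    values = rng.standard_normal((n_epochs, n_windows, n_features))
    values[labels == "A", :, 0] += effect  # one informative feature
    meta = pd.DataFrame(
        {"modality": "EEG", "channel": [f"c{i}" for i in range(n_features)],
         "subtype": "theta"}
    )
    return WindowedFeatureMatrix(values, np.arange(n_windows, dtype=float), meta, labels)


def test_cv_estimate_count_and_signal(rng):
    feats = _toy_features(rng)
    res = ns.run_windowed_cv(feats, ("A", "B"), ns.CVScheme(10, 10, seed=3))
    assert (res.perf["n_estimates"] == 100).all()
    assert res.kappas.shape == (2, 100)
    assert (res.perf["mean_kappa"] > 0.5).all()


def test_cv_permuted_labels_near_zero(rng):
    feats = _toy_features(rng)
    perm = rng.permutation(len(feats.labels))
    feats_null = WindowedFeatureMatrix(
        feats.values, feats.window_starts, feats.meta, feats.labels[perm]
    )
    res = ns.run_windowed_cv(feats_null, ("A", "B"), ns.CVScheme(10, 10, seed=4))
    assert np.abs(res.perf["mean_kappa"]).max() < 0.15


def test_cv_requires_two_examples_per_class(rng):
    feats = _toy_features(rng, n_epochs=96)
    labels = feats.labels.copy()
    labels[labels == "B"] = "A"
    labels[0] = "B"
    bad = WindowedFeatureMatrix(feats.values, feats.window_starts, feats.meta, labels)
    with pytest.raises(ConfigurationError):
        ns.run_windowed_cv(bad, ("A", "B"))


# -------------------------------------------------------------------- fusion

def test_fusion_counts(small_features):
    eeg, nirs = small_features
    fused = ns.fuse_feature_sets(eeg, nirs)
    assert fused.n_features == 839
    counts = fused.meta["modality"].value_counts()
    assert counts["EEG"] == 620 and counts["NIRS"] == 219


def test_fusion_with_zero_features_matches_single_modality(rng):
    feats = _toy_features(rng, n_windows=1)
    zeros = WindowedFeatureMatrix(
        np.zeros((feats.n_epochs, 1, 3)), feats.window_starts,
        pd.DataFrame({"modality": "NIRS", "channel": ["z0", "z1", "z2"],
                      "subtype": "HbO"}),
        feats.labels,
    )
    fused = ns.fuse_feature_sets(feats, zeros)
    r1 = ns.run_windowed_cv(feats, ("A", "B"), ns.CVScheme(3, 5, seed=9))
    r2 = ns.run_windowed_cv(fused, ("A", "B"), ns.CVScheme(3, 5, seed=9))
    assert abs(r1.perf["mean_kappa"].iloc[0] - r2.perf["mean_kappa"].iloc[0]) < 0.05


def test_fusion_alignment_errors(small_features, rng):
    eeg, nirs = small_features
    with pytest.raises(ns.AlignmentError):
        ns.fuse_feature_sets(eeg, nirs.select_epochs(np.arange(nirs.n_epochs - 1)))


# ------------------------------------------------------------- peak summaries

def _perf(mean_kappas, starts=None):
    starts = starts if starts is not None else np.arange(-5.0, 20.0)
    return pd.DataFrame({"window_start_s": starts, "mean_kappa": mean_kappas})


def test_peak_summary_basics():
    kappas = np.zeros(25)
    kappas[8] = 0.8  # window [3, 4): index 8 with starts -5..19
    peak = ns.peak_summary(_perf(kappas))
    assert peak.peak_kappa == 0.8 and peak.peak_time_s == 3.0
    const = ns.peak_summary(_perf(np.full(25, 0.5)))
    assert const.peak_kappa == 0.5 and const.peak_time_s == 0.0  # earliest tie
    post = np.zeros(25)
    post[21] = 0.9  # [16, 17): outside the task
    post[7] = 0.3
    peak2 = ns.peak_summary(_perf(post))
    assert peak2.peak_kappa == 0.3 and peak2.peak_time_s == 2.0
    with pytest.raises(ConfigurationError):
        ns.peak_summary(_perf(np.zeros(10), starts=np.arange(-5.0, 5.0)))


def test_delta_kappa_at_window():
    a = _perf(np.full(25, 0.62))
    b = _perf(np.full(25, 0.42))
    assert ns.delta_kappa_at_window(a, b, 11.0) == pytest.approx(0.20)
    assert ns.delta_kappa_at_window(a, a, 5.0) == 0.0
    with pytest.raises(ConfigurationError):
        ns.delta_kappa_at_window(a, b, 99.0)
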