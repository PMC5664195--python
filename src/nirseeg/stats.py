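"""Group statistics: task-pair ranking, fusion tests, weight importance.

Task pairs are ranked by the one-sample t-statistic of their per-subject peak
kappas against the satisfactory-performance threshold kappa_0 = 0.4; the
Holm-Bonferroni step-down controls the family-wise error over the 21 pairs.
The benefit of adding NIRS features to EEG is assessed with two-tailed paired
t-tests per pair, again Holm-corrected.  Because features are Z-normalized
before training, the absolute weights of the sparse linear models act as
feature importances; they are averaged over models and aggregated per channel
and per subtype (band, ratio or chromophore).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError

__all__ = [
    "holm_bonferroni",
    "significance_stars",
    "rank_task_pairs",
    "paired_fusion_test",
    "feature_importance",
]

log = logging.getLogger(__name__)


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm's step-down multiple-comparison correction.

    Sorts the m p-values ascending and compares the i-th smallest to
    alpha / (m - i); rejection stops at the first failure.  Returns
    (reject flags, adjusted p-values); adjusted p-values are the running
    maximum of (m - i) * p_(i), clipped to 1, so they are monotone and
    adjusted significance implies raw significance.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ConfigurationError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    reject = np.zeros(m, dtype=bool)
    running = 0.0
    still_rejecting = True
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adjusted[idx] = min(1.0, running)
        if still_rejecting and p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            still_rejecting = False
    return reject, adjusted


def significance_stars(p_adjusted: float) -> str:
    """Tier marks: *, **, *** for adjusted p < 0.05, 0.01, 0.001."""
    if p_adjusted < 0.001:
        return "***"
    if p_adjusted < 0.01:
        return "**"
    if p_adjusted < 0.05:
        return "*"
    return ""


def _one_sample_t(values: np.ndarray, popmean: float) -> tuple[float, float]:
    sd = values.std(ddof=1)
    if sd == 0:
        # zero-variance sample: sign of the mean decides, t degenerates
        log.warning("zero-variance kappa vector; t treated as +/-inf")
        diff = values.mean() - popmean
        if diff == 0:
            return 0.0, 1.0
        return float(np.inf) if diff > 0 else float(-np.inf), 0.0
    res = sps.ttest_1samp(values, popmean)
    return float(res.statistic), float(res.pvalue)


def rank_task_pairs(
    peaks: pd.DataFrame, kappa0: float = 0.4, alpha: float = 0.05
) -> pd.DataFrame:
    """Rank task pairs by their one-sample t-statistic against ``kappa0``.

    ``peaks``: rows = task pairs, columns = subjects, values = peak kappa.
    Returns a table with mean, sd, t, raw and Holm-adjusted p, significance
    stars, and rank (1 = largest t).  Needs >= 2 subjects.
    """
    if peaks.shape[1] < 2:
        raise ConfigurationError("ranking needs at least 2 subjects per pair")
    rows = []
    for pair, values in peaks.iterrows():
        v = values.to_numpy(dtype=float)
        t, p = _one_sample_t(v, kappa0)
        rows.append((pair, v.mean(), v.std(ddof=1), t, p))
    out = pd.DataFrame(rows, columns=["pair", "mean_kappa", "sd_kappa", "t", "p_raw"])
    reject, adjusted = holm_bonferroni(out["p_raw"].to_numpy(), alpha)
    out["p_holm"] = adjusted
    out["significant"] = reject
    out["stars"] = [significance_stars(p) for p in adjusted]
    # rank 1 = greatest t; stable order for ties
    order = np.argsort(-out["t"].to_numpy(), kind="stable")
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    return out.sort_values("rank").reset_index(drop=True)


def paired_fusion_test(
    peaks_eeg: pd.DataFrame, peaks_fused: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-tailed paired t-tests (fused vs EEG peaks) per pair, Holm-corrected.

    Both tables must share pairs (rows) and subjects (columns).
    """
    if not peaks_eeg.index.equals(peaks_fused.index) or not peaks_eeg.columns.equals(
        peaks_fused.columns
    ):
        raise ConfigurationError("EEG and fused peak tables must be aligned")
    if peaks_eeg.shape[1] < 2:
        raise ConfigurationError("paired test needs at least 2 subjects")
    rows = []
    for pair in peaks_eeg.index:
        a = peaks_fused.loc[pair].to_numpy(dtype=float)
        b = peaks_eeg.loc[pair].to_numpy(dtype=float)
        diff = a - b
        if np.allclose(diff, diff[0]):
            if diff[0] == 0:
                t, p = 0.0, 1.0
            else:
                log.warning("constant paired difference; t treated as +/-inf")
                t, p = (np.inf if diff[0] > 0 else -np.inf), 0.0
        else:
            res = sps.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append((pair, diff.mean(), t, p))
    out = pd.DataFrame(rows, columns=["pair", "mean_delta_kappa", "t", "p_raw"])
    reject, adjusted = holm_bonferroni(out["p_raw"].to_numpy(), alpha)
    out["p_holm"] = adjusted
    out["significant"] = reject
    out["stars"] = [significance_stars(p) for p in adjusted]
    return out


def feature_importance(
    weight_sets: np.ndarray, meta: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Mean |w| per feature across models, with channel/subtype aggregates.

    ``weight_sets`` is (n_models, n_features) in the shared feature space;
    ``meta`` carries (modality, channel, subtype) per feature.  Channel and
    subtype aggregates are means over their member features, so channels
    contributing different feature counts remain comparable.  Returns
    {'features': ..., 'channels': ..., 'subtypes': ...}, each ranked
    descending with stable tie-breaks.
    """
    w = np.atleast_2d(np.asarray(weight_sets, dtype=float))
    if w.shape[1] != len(meta):
        raise ConfigurationError("weight sets and metadata describe different feature spaces")
    imp = np.abs(w).mean(axis=0)
    feat = meta.copy()
    feat["importance"] = imp
    feat["rank"] = (
        feat["importance"].rank(method="first", ascending=False).astype(int)
    )
    channels = (
        feat.groupby(["modality", "channel"], sort=False)["importance"]
        .mean()
        .reset_index()
    )
    channels["rank"] = channels["importance"].rank(method="first", ascending=False).astype(int)
    subtypes = (
        feat.groupby(["modality", "subtype"], sort=False)["importance"].mean().reset_index()
    )
    subtypes["rank"] = subtypes["importance"].rank(method="first", ascending=False).astype(int)
    return {
        "features": feat.sort_values("rank").reset_index(drop=True),
        "channels": channels.sort_values("rank").reset_index(drop=True),
        "subtypes": subtypes.sort_values("rank").reset_index(drop=True),
    }
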