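"""Informational connectivity from trial-wise pattern discriminability.

For each ROI a leave-one-trial-out classifier produces a per-volume
*discriminability* series: the probability the trained classifier assigns to
the left-out trial's true category at every volume of that trial.  Pairwise
Pearson correlations between ROIs' series form the informational-connectivity
(IC) matrix; the same correlations between ROI-mean BOLD time courses form
the functional-connectivity (FC) control.  A permutation effect size
(observed r minus null mean, divided by the null variance) makes the IC
statistic independent of the overall level of decoding accuracy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .decoding import ClassifierSpec
from .preprocess import BoldRun, _window_indices, extract_trial_volume_series
from .stats import attach_fdr, paired_t

__all__ = [
    "DiscriminabilityTimeSeries",
    "ConnectivityMatrix",
    "PermEffectSize",
    "discriminability_timeseries",
    "informational_connectivity",
    "functional_connectivity",
    "permutation_effect_size",
    "condition_contrast",
]


@dataclass
class DiscriminabilityTimeSeries:
    """Per-volume probability of the correct class for one ROI/condition."""

    roi: str
    condition: str
    values: np.ndarray
    volume_index: list      # (run_id, volume index) per value

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("discriminability values must lie in [0, 1]")


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson matrix (diagonal masked as NaN)."""

    rois: list
    r: np.ndarray
    kind: str               # "informational" or "functional"
    condition: str

    def pair(self, a: str, b: str) -> float:
        return float(self.r[self.rois.index(a), self.rois.index(b)])

    def to_frame(self, subject: str = "") -> pd.DataFrame:
        rows = []
        for i, j in itertools.combinations(range(len(self.rois)), 2):
            rows.append({"roi_a": self.rois[i], "roi_b": self.rois[j],
                         "r": float(self.r[i, j]), "kind": self.kind,
                         "condition": self.condition, "subject": subject})
        return pd.DataFrame(rows)


@dataclass
class PermEffectSize:
    """Shuffle-null effect size for one ROI pair's IC correlation."""

    pair: tuple
    r_true: float
    null_mean: float
    null_var: float
    effect: float
    n_perm: int


def _train_probability_model(Ztr, ytr, spec: ClassifierSpec):
    clf = spec.build().fit(Ztr, ytr)
    if spec.probability_mode == "platt":
        d = clf.decision_function(Ztr).reshape(-1, 1)
        calib = LogisticRegression().fit(d, ytr)

        def predict_proba(Z):
            return calib.predict_proba(clf.decision_function(Z).reshape(-1, 1))

        return predict_proba, calib.classes_
    # sigmoid of the decision value, oriented to clf.classes_[1]
    def predict_proba(Z):
        p1 = expit(clf.decision_function(Z))
        return np.column_stack([1.0 - p1, p1])

    return predict_proba, clf.classes_


def discriminability_timeseries(runs: list[BoldRun],
                                events: list[pd.DataFrame],
                                spec: ClassifierSpec | None = None,
                                condition: str | None = None
                                ) -> DiscriminabilityTimeSeries:
    """Leave-one-trial-out discriminability series for one ROI.

    Training samples are the individual volumes inside every remaining
    trial's 3.4-6.8 s window, labelled by that trial's category; the trained
    PCA + linear-SVM pipeline (with Platt-calibrated probabilities by
    default) is then applied to *all* volumes of the left-out trial, and the
    probability assigned to the trial's true category is recorded per volume.
    Values are concatenated in volume order.  Volumes before the first trial
    onset are excluded; catch trials are skipped.
    """
    spec = spec or ClassifierSpec()
    spec.validate()
    roi = runs[0].roi_id if runs else ""
    if condition is None:
        conds = {r.condition for r in runs if r.condition is not None}
        condition = conds.pop() if len(conds) == 1 else "mixed"
    series = extract_trial_volume_series(runs, events, include_catch=False)
    run_lookup = {r.run_id: r for r in runs}

    # Classifier-window training samples per trial.
    skipped = []
    trials = []
    for ts in series:
        run = run_lookup[ts.run_id]
        win = _window_indices(ts.onset, run.tr, run.n_volumes)
        if win is None:
            skipped.append((ts.run_id, ts.word))
            continue
        idx, cls_mask = win
        trials.append((ts, run.data[:, idx[cls_mask]].T))  # (n_win, n_vox)
    if skipped:
        warnings.warn(f"{len(skipped)} trial(s) with empty training window "
                      f"skipped: {skipped[:3]}...", stacklevel=2)
    labels = np.array([ts.category for ts, _ in trials])
    if min((labels == c).sum() for c in np.unique(labels)) < 2:
        raise ValueError("need at least two trials per class")

    values, vol_index = [], []
    for held in range(len(trials)):
        Xtr = np.concatenate(
            [w for k, (_, w) in enumerate(trials) if k != held])
        ytr = np.concatenate(
            [[ts.category] * w.shape[0]
             for k, (ts, w) in enumerate(trials) if k != held])
        pca = PCA(n_components=min(Xtr.shape), svd_solver="full")
        Ztr = pca.fit_transform(Xtr)
        predict_proba, classes = _train_probability_model(Ztr, ytr, spec)
        ts, _ = trials[held]
        proba = predict_proba(pca.transform(ts.data.T))
        true_col = int(np.flatnonzero(classes == ts.category)[0])
        values.extend(proba[:, true_col])
        vol_index.extend((ts.run_id, int(v)) for v in ts.volume_indices)
    order = np.lexsort(([v for _, v in vol_index],
                        [r for r, _ in vol_index]))
    return DiscriminabilityTimeSeries(
        roi=roi, condition=condition,
        values=np.asarray(values)[order],
        volume_index=[vol_index[i] for i in order])


def _pearson_matrix(series: list[np.ndarray]) -> np.ndarray:
    n = len(series)
    r = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        a, b = series[i], series[j]
        if a.std() == 0 or b.std() == 0:
            continue                        # undefined: stays NaN
        r[i, j] = r[j, i] = float(np.corrcoef(a, b)[0, 1])
    return r


def informational_connectivity(ts_list: list[DiscriminabilityTimeSeries]
                               ) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of discriminability series."""
    if len(ts_list) < 2:
        raise ValueError("need at least two ROIs")
    lengths = {ts.values.size for ts in ts_list}
    if len(lengths) != 1:
        raise ValueError("series lengths differ across ROIs")
    ref = ts_list[0].volume_index
    for ts in ts_list[1:]:
        if ts.volume_index != ref:
            raise ValueError("series are not volume-aligned")
    conds = {ts.condition for ts in ts_list}
    cond = conds.pop() if len(conds) == 1 else "mixed"
    return ConnectivityMatrix(
        rois=[ts.roi for ts in ts_list],
        r=_pearson_matrix([ts.values for ts in ts_list]),
        kind="informational", condition=cond)


def functional_connectivity(runs_by_roi: dict,
                            condition: str | None = None
                            ) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of ROI-mean BOLD time courses.

    ``runs_by_roi`` maps ROI name to its list of (normalized) runs; runs must
    share the scan grid across ROIs.  Mean time courses are concatenated over
    runs before correlating.
    """
    if len(runs_by_roi) < 2:
        raise ValueError("need at least two ROIs")
    means = {}
    n_runs = None
    for roi, runs in runs_by_roi.items():
        if not runs:
            raise ValueError(f"empty ROI {roi!r}")
        if n_runs is None:
            n_runs = len(runs)
        elif len(runs) != n_runs:
            raise ValueError("ROIs have different run counts")
        means[roi] = np.concatenate([r.data.mean(axis=0) for r in runs])
    lengths = {m.size for m in means.values()}
    if len(lengths) != 1:
        raise ValueError("ROIs do not share the scan grid")
    if condition is None:
        conds = {r.condition for runs in runs_by_roi.values() for r in runs}
        condition = conds.pop() if len(conds) == 1 else "mixed"
    rois = list(means)
    return ConnectivityMatrix(rois=rois,
                              r=_pearson_matrix([means[r] for r in rois]),
                              kind="functional", condition=condition)


def permutation_effect_size(ts_a, ts_b, n_perm: int = 10000, seed=None,
                            use_sd: bool = False,
                            pair: tuple = ("a", "b")) -> PermEffectSize:
    """Accuracy-independent IC effect size from a shuffle null.

    The first series is randomly shuffled ``n_perm`` times and correlated
    with the intact second series; the effect is the observed correlation
    minus the null mean, divided by the null *variance* (the stated formula;
    ``use_sd=True`` divides by the standard deviation instead).
    """
    a = np.asarray(getattr(ts_a, "values", ts_a), dtype=float)
    b = np.asarray(getattr(ts_b, "values", ts_b), dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("series must share a length of at least 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant series: correlation undefined")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    r_true = float(az @ bz / a.size)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = az[rng.permutation(a.size)] @ bz / a.size
    null_mean = float(null.mean())
    null_var = float(null.var(ddof=1))
    denom = np.sqrt(null_var) if use_sd else null_var
    return PermEffectSize(pair=pair, r_true=r_true, null_mean=null_mean,
                          null_var=null_var,
                          effect=float((r_true - null_mean) / denom),
                          n_perm=n_perm)


def condition_contrast(matrices_deep: list[ConnectivityMatrix],
                       matrices_shallow: list[ConnectivityMatrix],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Paired t per ROI pair on deep - shallow connectivity across subjects.

    Inputs are per-subject matrices, matched in order.  Pairs with missing
    (NaN) entries in any subject are excluded and reported in the
    ``excluded`` column of the returned table's attrs.
    """
    if len(matrices_deep) != len(matrices_shallow):
        raise ValueError("condition lists must be subject-matched")
    if len(matrices_deep) < 3:
        raise ValueError("need at least 3 subjects")
    rois = matrices_deep[0].rois
    for m in matrices_deep + matrices_shallow:
        if m.rois != rois:
            raise ValueError("ROI sets differ across matrices")
    family, meta, excluded = [], [], []
    for i, j in itertools.combinations(range(len(rois)), 2):
        deep = np.array([m.r[i, j] for m in matrices_deep])
        shallow = np.array([m.r[i, j] for m in matrices_shallow])
        if np.any(~np.isfinite(deep)) or np.any(~np.isfinite(shallow)):
            excluded.append((rois[i], rois[j]))
            continue
        family.append(paired_t(deep, shallow, name=f"{rois[i]}-{rois[j]}"))
        meta.append({"roi_a": rois[i], "roi_b": rois[j],
                     "mean_deep": float(deep.mean()),
                     "mean_shallow": float(shallow.mean())})
    attach_fdr(family, alpha=alpha)
    table = pd.DataFrame([{**m, **r.as_dict()}
                          for m, r in zip(meta, family)])
    table.attrs["excluded"] = excluded
    return table
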