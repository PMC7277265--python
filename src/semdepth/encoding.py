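"""Voxelwise ridge encoding of stimulus feature spaces onto trial responses.

Word-level feature matrices (word-embedding or computer-vision model outputs,
300-D by convention) are expanded to trials, standardized on each training
fold, and mapped to voxel responses by ridge regression (alpha = 100).  Model
quality is the per-voxel coefficient of determination (R-squared, at most 1,
negative when the model is worse than predicting the mean) averaged over
repeated stratified 80/20 folds; category labels are used only to stratify
folds, never in fitting.  An empirical chance level repeats the identical
pipeline with the training-fold feature rows shuffled against intact targets.

Also here: representational dissimilarity matrices (RDMs) and the
model-family comparison statistics (within-family ANOVA, pairwise
vision-vs-embedding contrasts, condition contrasts, bootstrap CIs,
positive-voxel reports).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.metrics import r2_score
from sklearn.preprocessing import StandardScaler

from .decoding import make_stratified_splits
from .preprocess import TrialExamples
from .simulate import FeatureMatrix, expand_features_to_trials
from .stats import (attach_fdr, bootstrap_ci_mean, one_sample_t,
                    one_way_anova, paired_t)

__all__ = [
    "EncodingSpec",
    "EncodingResult",
    "RDM",
    "fit_encoding",
    "empirical_chance",
    "EncodingModel",
    "EncodingResults",
    "compute_rdm",
    "compare_models",
    "positive_voxel_report",
]


@dataclass
class EncodingSpec:
    """Ridge encoding configuration (alpha = 100, 300 stratified folds)."""

    alpha: float = 100.0
    n_folds: int = 300
    test_fraction: float = 0.2
    seed: int | None = None

    def validate(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")


@dataclass
class EncodingResult:
    """Per-voxel variance explained and its aggregates for one model fit."""

    roi: str
    condition: str
    model_name: str
    voxel_ve: np.ndarray            # mean R-squared across folds, per voxel
    n_folds: int
    chance_ve: float | None = None
    fold_predictions: list = field(default_factory=list, repr=False)

    @property
    def positive_voxels(self) -> np.ndarray:
        return np.flatnonzero(self.voxel_ve > 0)

    @property
    def aggregate_ve(self) -> float:
        """Mean VE over positive voxels (0.0 when no voxel is positive)."""
        pos = self.positive_voxels
        return float(self.voxel_ve[pos].mean()) if pos.size else 0.0

    @property
    def aggregate_ve_all(self) -> float:
        """Mean VE over all voxels."""
        return float(self.voxel_ve.mean())


@dataclass
class RDM:
    """Word x word representational dissimilarity matrix."""

    model_name: str
    matrix: np.ndarray
    metric: str
    words: np.ndarray | None = None
    degenerate_words: list = field(default_factory=list)


def _resolve_inputs(features, examples):
    """Align feature rows to trials and pull targets + labels."""
    if isinstance(examples, TrialExamples):
        targets = np.asarray(examples.features, dtype=float)
        labels = np.asarray(examples.labels)
        trial_words = examples.words
        roi = examples.roi
        conds = np.unique(examples.conditions)
        condition = conds[0] if conds.size == 1 else "mixed"
    else:
        targets, labels = examples
        targets = np.asarray(targets, dtype=float)
        labels = np.asarray(labels)
        trial_words = None
        roi, condition = "", ""
    if isinstance(features, FeatureMatrix):
        if features.matrix.shape[0] != targets.shape[0]:
            if trial_words is None:
                raise ValueError("feature rows are not aligned to trials")
            features = expand_features_to_trials(features, trial_words)
        X = features.matrix
        model_name = features.model_name
    else:
        X = np.asarray(features, dtype=float)
        model_name = "features"
    if X.shape[0] != targets.shape[0]:
        raise ValueError("feature rows are not aligned to trials")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(targets))):
        raise ValueError("non-finite inputs")
    return X, targets, labels, model_name, roi, condition


def fit_encoding(features, examples, spec: EncodingSpec | None = None,
                 shuffle_train: bool = False,
                 keep_fold_predictions: bool = False) -> EncodingResult:
    """Cross-validated ridge encoding fit.

    Parameters
    ----------
    features : FeatureMatrix (word- or trial-level) or plain trial x dim array.
    examples : TrialExamples, or a ``(targets, labels)`` tuple of the
        trial x voxel target matrix and the stratification labels.
    spec : ridge penalty / fold configuration.
    shuffle_train : when True, each fold's training feature rows are randomly
        permuted against intact targets (the empirical-chance pipeline).
    keep_fold_predictions : retain per-fold ``(test_indices, predictions)``
        for oracle checks.

    Per fold: standardize features on the training rows, fit ridge
    (penalty ``alpha``), score per-voxel R-squared on the held-out rows.
    ``voxel_ve`` is the per-voxel mean across folds.
    """
    spec = spec or EncodingSpec()
    spec.validate()
    X, Y, labels, model_name, roi, condition = _resolve_inputs(
        features, examples)
    if X.shape[0] < 10:
        raise ValueError("encoding requires at least 10 trials")
    rng = np.random.default_rng(spec.seed)
    splits = make_stratified_splits(labels, n_splits=spec.n_folds,
                                    test_fraction=spec.test_fraction,
                                    seed=rng)
    ve_sum = np.zeros(Y.shape[1])
    fold_predictions = []
    for split in splits:
        tr, te = split.train_indices, split.test_indices
        Xtr = X[tr]
        if shuffle_train:
            Xtr = Xtr[rng.permutation(Xtr.shape[0])]
        scaler = StandardScaler().fit(Xtr)
        model = Ridge(alpha=spec.alpha).fit(scaler.transform(Xtr), Y[tr])
        pred = model.predict(scaler.transform(X[te]))
        ve_sum += r2_score(Y[te], pred, multioutput="raw_values")
        if keep_fold_predictions:
            fold_predictions.append((te, pred))
    return EncodingResult(roi=roi, condition=condition,
                          model_name=model_name,
                          voxel_ve=ve_sum / len(splits),
                          n_folds=len(splits),
                          fold_predictions=fold_predictions)


def empirical_chance(features, examples,
                     spec: EncodingSpec | None = None) -> float:
    """Aggregate VE of the shuffled-training-features control pipeline."""
    return fit_encoding(features, examples, spec,
                        shuffle_train=True).aggregate_ve_all


class EncodingResults:
    """Fit output of :class:`EncodingModel` with chance and a summary."""

    def __init__(self, result: EncodingResult, spec: EncodingSpec):
        self.result = result
        self.spec = spec

    def __getattr__(self, name):
        return getattr(self.result, name)

    def to_frame(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame({
            "roi": r.roi, "condition": r.condition, "model": r.model_name,
            "voxel": np.arange(r.voxel_ve.size), "ve": r.voxel_ve,
        })

    def summary(self) -> str:
        r = self.result
        lines = [
            "Ridge encoding results",
            "=" * 44,
            f"ROI:                  {r.roi or '-'}",
            f"Condition:            {r.condition or '-'}",
            f"Model:                {r.model_name}",
            f"Folds:                {r.n_folds} "
            f"(stratified {1 - self.spec.test_fraction:.0%}/"
            f"{self.spec.test_fraction:.0%}, alpha={self.spec.alpha:g})",
            f"Positive voxels:      {r.positive_voxels.size} / "
            f"{r.voxel_ve.size}",
            f"Mean VE (positive):   {r.aggregate_ve:.4f}",
            f"Mean VE (all voxels): {r.aggregate_ve_all:.4f}",
        ]
        if r.chance_ve is not None:
            lines.append(f"Empirical chance VE:  {r.chance_ve:.4f}")
        return "\n".join(lines)


class EncodingModel:
    """Voxelwise ridge encoding model for one ROI and one feature space.

    Parameters
    ----------
    features : FeatureMatrix or trial x dimension array.
    examples : TrialExamples or ``(targets, labels)`` tuple.
    spec : EncodingSpec (alpha, folds, test fraction, seed).
    """

    def __init__(self, features, examples, spec: EncodingSpec | None = None):
        self.features = features
        self.examples = examples
        self.spec = spec or EncodingSpec()

    def fit(self, with_chance: bool = False,
            keep_fold_predictions: bool = False) -> EncodingResults:
        result = fit_encoding(self.features, self.examples, self.spec,
                              keep_fold_predictions=keep_fold_predictions)
        if with_chance:
            result.chance_ve = empirical_chance(self.features, self.examples,
                                                self.spec)
        return EncodingResults(result, self.spec)


def compute_rdm(features: FeatureMatrix, metric: str = "correlation") -> RDM:
    """Representational dissimilarity matrix over word feature vectors.

    Feature dimensions are mean-centred across words first; dissimilarity is
    ``1 - Pearson r`` between word rows (``metric="cosine"`` uses
    ``1 - cosine``).  Words whose centred vector has zero variance produce
    undefined entries (NaN) and are listed in ``degenerate_words``.
    """
    if metric not in ("correlation", "cosine"):
        raise ValueError("metric must be 'correlation' or 'cosine'")
    M = features.matrix
    if M.shape[0] < 2:
        raise ValueError("RDM requires at least two words")
    M = M - M.mean(axis=0, keepdims=True)
    n = M.shape[0]
    out = np.zeros((n, n))
    if metric == "correlation":
        rows = M - M.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(rows, axis=1)
    else:
        rows = M
        norms = np.linalg.norm(rows, axis=1)
    bad = norms == 0
    norms_safe = np.where(bad, 1.0, norms)
    sim = (rows / norms_safe[:, None]) @ (rows / norms_safe[:, None]).T
    out = 1.0 - sim
    out[bad, :] = np.nan
    out[:, bad] = np.nan
    np.fill_diagonal(out, 0.0)
    out[~np.isnan(out)] = np.clip(out[~np.isnan(out)], 0.0, 2.0)
    return RDM(model_name=features.model_name, matrix=out, metric=metric,
               words=features.words,
               degenerate_words=[str(w) for w in features.words[bad]])


def _require_grid(df: pd.DataFrame, cols):
    """Check the subject x model (x roi x condition) grid is complete."""
    counts = df.groupby(list(cols), observed=True).size()
    if counts.nunique() > 1:
        missing = counts[counts < counts.max()]
        raise ValueError(f"unbalanced grid; incomplete cells: "
                         f"{missing.index.tolist()}")


def compare_models(results: pd.DataFrame, alpha: float = 0.05,
                   n_boot: int = 1000, seed: int | None = None) -> dict:
    """Model-family comparison over a tidy table of aggregate VE values.

    ``results`` needs columns ``subject``, ``roi``, ``condition``, ``model``,
    ``family`` (embedding / vision) and ``ve`` — one row per cell.  Returns a
    dict of tables:

    * ``anova`` — within-family one-way ANOVA across models per ROI and
      condition, FDR over ROIs within condition (and family);
    * ``pairwise`` — every vision-minus-embedding per-subject difference
      tested against zero, FDR-corrected;
    * ``condition_contrast`` — mean family difference, deep vs shallow,
      paired t per ROI with FDR;
    * ``ci`` — bootstrap 95% CI of the mean VE per ROI/condition/model.
    """
    needed = {"subject", "roi", "condition", "model", "family", "ve"}
    if not needed.issubset(results.columns):
        raise ValueError(f"results table needs columns {sorted(needed)}")
    _require_grid(results, ["roi", "condition", "model"])
    subjects = np.sort(results["subject"].unique())

    def cell(roi, cond, model):
        sub = results[(results["roi"] == roi) & (results["condition"] == cond)
                      & (results["model"] == model)]
        return sub.set_index("subject").loc[subjects, "ve"].to_numpy()

    rois = np.sort(results["roi"].unique())
    conds = np.sort(results["condition"].unique())
    families = {f: np.sort(results.loc[results["family"] == f,
                                       "model"].unique())
                for f in results["family"].unique()}

    anova_rows = []
    for cond in conds:
        for fam, models in families.items():
            tests, meta = [], []
            for roi in rois:
                groups = [cell(roi, cond, m) for m in models]
                if len(groups) < 2:
                    continue
                tests.append(one_way_anova(*groups, name=f"{roi}"))
                meta.append({"roi": roi, "condition": cond, "family": fam})
            attach_fdr(tests, alpha=alpha)
            anova_rows += [{**m, **t.as_dict()}
                           for m, t in zip(meta, tests)]

    pair_rows = []
    if {"vision", "embedding"}.issubset(families):
        tests, meta = [], []
        for cond in conds:
            for roi in rois:
                for vm in families["vision"]:
                    for em in families["embedding"]:
                        diff = cell(roi, cond, vm) - cell(roi, cond, em)
                        tests.append(one_sample_t(
                            diff, 0.0, name=f"{roi}|{cond}|{vm}-{em}"))
                        meta.append({"roi": roi, "condition": cond,
                                     "vision_model": vm,
                                     "embedding_model": em,
                                     "mean_diff": float(diff.mean())})
        attach_fdr(tests, alpha=alpha)
        pair_rows = [{**m, **t.as_dict()} for m, t in zip(meta, tests)]

    contrast_rows = []
    if {"vision", "embedding"}.issubset(families) \
            and {"deep", "shallow"}.issubset(set(conds)):
        tests, meta = [], []
        for roi in rois:
            fam_diff = {}
            for cond in ("deep", "shallow"):
                diffs = [cell(roi, cond, vm) - cell(roi, cond, em)
                         for vm in families["vision"]
                         for em in families["embedding"]]
                fam_diff[cond] = np.mean(diffs, axis=0)
            tests.append(paired_t(fam_diff["deep"], fam_diff["shallow"],
                                  name=str(roi)))
            meta.append({"roi": roi,
                         "mean_deep": float(fam_diff["deep"].mean()),
                         "mean_shallow": float(fam_diff["shallow"].mean())})
        attach_fdr(tests, alpha=alpha)
        contrast_rows = [{**m, **t.as_dict()} for m, t in zip(meta, tests)]

    rng = np.random.default_rng(seed)
    ci_rows = []
    for cond in conds:
        for roi in rois:
            for model in np.sort(results["model"].unique()):
                vals = cell(roi, cond, model)
                lo, hi = bootstrap_ci_mean(
                    vals, n_iter=n_boot,
                    seed=int(rng.integers(2 ** 31)))
                ci_rows.append({"roi": roi, "condition": cond,
                                "model": model, "mean_ve": float(vals.mean()),
                                "ci_lo": lo, "ci_hi": hi})

    return {"anova": pd.DataFrame(anova_rows),
            "pairwise": pd.DataFrame(pair_rows),
            "condition_contrast": pd.DataFrame(contrast_rows),
            "ci": pd.DataFrame(ci_rows)}


def positive_voxel_report(results_by_model: dict,
                          alpha: float = 0.05) -> dict:
    """Positive-VE voxel counts and cross-model overlap statistics.

    ``results_by_model`` maps model name to a subject-aligned list of
    :class:`EncodingResult`.  Returns ``counts`` (per subject and model),
    ``count_tests`` (paired t on count differences, FDR-corrected) and
    ``overlap`` (of voxels positive under model A, the mean fraction also
    positive under B and the fraction where B explains more variance).
    """
    models = list(results_by_model)
    if len(models) < 2:
        raise ValueError("need at least two models")
    n_subj = {len(v) for v in results_by_model.values()}
    if len(n_subj) != 1:
        raise ValueError("models have different subject counts")
    counts = pd.DataFrame({
        m: [len(r.positive_voxels) for r in results_by_model[m]]
        for m in models})
    counts.index.name = "subject"

    tests, meta = [], []
    overlap_rows = []
    for a, b in itertools.combinations(models, 2):
        ca, cb = counts[a].to_numpy(float), counts[b].to_numpy(float)
        tests.append(paired_t(ca, cb, name=f"{a}-{b}"))
        meta.append({"model_a": a, "model_b": b,
                     "mean_count_a": float(ca.mean()),
                     "mean_count_b": float(cb.mean())})
    for a, b in itertools.permutations(models, 2):
        fr_pos, fr_higher = [], []
        for ra, rb in zip(results_by_model[a], results_by_model[b]):
            pos_a = ra.positive_voxels
            if pos_a.size == 0:
                continue
            fr_pos.append(float(np.mean(rb.voxel_ve[pos_a] > 0)))
            fr_higher.append(float(np.mean(
                rb.voxel_ve[pos_a] > ra.voxel_ve[pos_a])))
        overlap_rows.append({
            "model_a": a, "model_b": b,
            "frac_also_positive": float(np.mean(fr_pos)) if fr_pos
            else np.nan,
            "frac_higher": float(np.mean(fr_higher)) if fr_higher
            else np.nan})
    attach_fdr(tests, alpha=alpha)
    count_tests = pd.DataFrame([{**m, **t.as_dict()}
                                for m, t in zip(meta, tests)])
    return {"counts": counts, "count_tests": count_tests,
            "overlap": pd.DataFrame(overlap_rows)}
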