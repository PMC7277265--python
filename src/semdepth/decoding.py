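"""ROI-wise binary category decoding: PCA + linear SVM under three CV schemes.

The classification pipeline follows the standard MVPA recipe: principal
components are fitted on the training examples only (component count equal to
the smaller of training-set size and voxel count, an information-lossless
rotation when voxels exceed examples), the projected training data feed an
L2-regularized linear support-vector classifier (C = 1.0, tol = 1e-4), and
accuracy is the fraction of correctly labelled held-out trials.

Cross-validation schemes:

* ``stratified`` — repeated class-balanced 80/20 shuffles (300 by default);
* ``word_pair`` — out-of-sample generalization: one word per class held out,
  so no test word ever appears in training;
* ``run`` — leave one run out.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.svm import LinearSVC

from .preprocess import TrialExamples
from .stats import StatResult, attach_fdr, one_sample_t, paired_t

__all__ = [
    "ClassifierSpec",
    "CvSplit",
    "DecodingResult",
    "make_stratified_splits",
    "make_word_pair_splits",
    "make_run_splits",
    "decode",
    "CategoryDecoder",
    "DecodingResults",
    "group_level_stats",
]


@dataclass
class ClassifierSpec:
    """Linear max-margin classifier configuration.

    Defaults reproduce the stated setup exactly: L2 penalty, C = 1.0,
    tolerance = 1e-4 (the liblinear squared-hinge variant; recorded in
    ``variant`` so outputs are self-describing).
    """

    penalty: str = "l2"
    cost: float = 1.0
    tolerance: float = 1e-4
    probability_mode: str = "platt"   # or "sigmoid_decision"
    variant: str = "liblinear squared-hinge"

    def validate(self):
        if self.penalty != "l2":
            raise ValueError("only the l2 penalty is supported")
        if self.cost <= 0 or self.tolerance <= 0:
            raise ValueError("cost and tolerance must be positive")
        if self.probability_mode not in ("platt", "sigmoid_decision"):
            raise ValueError("unknown probability_mode")

    def build(self) -> LinearSVC:
        self.validate()
        return LinearSVC(penalty=self.penalty, C=self.cost,
                         tol=self.tolerance, dual="auto", random_state=0)


@dataclass
class CvSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    scheme: str
    meta: object = None

    def __post_init__(self):
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test indices overlap")


@dataclass
class DecodingResult:
    roi: str
    condition: str
    scheme: str
    per_split_accuracy: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_split_accuracy))


def _round_ties_low(x: float) -> int:
    # Round half toward the smaller test set.
    frac = x - np.floor(x)
    return int(np.floor(x)) if abs(frac - 0.5) < 1e-12 else int(round(x))


def make_stratified_splits(labels, n_splits: int = 300,
                           test_fraction: float = 0.2,
                           seed=None) -> list[CvSplit]:
    """Repeated class-balanced train/test shuffles.

    Both sides of every split carry equal per-class counts: the per-class
    test size is ``round(class_size * test_fraction)`` (ties toward the
    smaller test set), equalized across classes by taking the minimum; the
    training side is likewise truncated to equal per-class counts.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 examples")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    test_k = min(_round_ties_low(c * test_fraction) for c in counts)
    if test_k < 1:
        raise ValueError("test_fraction too small for the class sizes")
    train_k = min(int(c) - test_k for c in counts)
    if train_k < 1:
        raise ValueError("no training examples left after the test split")
    splits = []
    for s in range(n_splits):
        train, test = [], []
        for cls in classes:
            idx = rng.permutation(np.flatnonzero(labels == cls))
            test.append(idx[:test_k])
            train.append(idx[test_k:test_k + train_k])
        splits.append(CvSplit(np.concatenate(train), np.concatenate(test),
                              "stratified_shuffle", meta=s))
    return splits


def make_word_pair_splits(words, labels, n_pairs: int | None = None,
                          seed=None) -> list[CvSplit]:
    """Out-of-sample splits: one word per class held out for testing.

    Enumerates every (living word, non-living word) pair by default
    (18 x 18 = 324 at the study's pool size); ``n_pairs`` subsamples the
    enumeration for speed.
    """
    words = np.asarray(words)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("word-pair splits require exactly two classes")
    by_class = {c: np.unique(words[labels == c]) for c in classes}
    for c, ws in by_class.items():
        for w in ws:
            if not np.any(words == w):
                raise ValueError(f"word {w!r} has no trials")
    pairs = list(itertools.product(by_class[classes[0]], by_class[classes[1]]))
    if n_pairs is not None and n_pairs < len(pairs):
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        keep = rng.choice(len(pairs), size=n_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(keep)]
    splits = []
    for wa, wb in pairs:
        test_mask = (words == wa) | (words == wb)
        train = np.flatnonzero(~test_mask)
        test = np.flatnonzero(test_mask)
        if train.size == 0:
            raise ValueError("empty training set: too few words per class")
        splits.append(CvSplit(train, test, "word_pair", meta=(wa, wb)))
    return splits


def make_run_splits(run_ids) -> list[CvSplit]:
    """Leave-one-run-out splits (one fold per run)."""
    run_ids = np.asarray(run_ids)
    runs = np.unique(run_ids)
    if runs.size < 2:
        raise ValueError("leave-one-run-out requires at least two runs")
    if runs.size <= 4:
        warnings.warn(
            f"only {runs.size} cross-validation folds: leave-one-run-out "
            "estimates can be unstable; repeated random splits are preferred",
            stacklevel=2)
    return [CvSplit(np.flatnonzero(run_ids != r), np.flatnonzero(run_ids == r),
                    "run", meta=str(r)) for r in runs]


def _fit_split(X, y, split: CvSplit, spec: ClassifierSpec):
    Xtr, ytr = X[split.train_indices], y[split.train_indices]
    Xte = X[split.test_indices]
    if np.unique(ytr).size < 2:
        raise ValueError("training set must contain both classes")
    if Xtr.shape[0] < 2:
        raise ValueError("PCA requires at least two training examples")
    pca = PCA(n_components=min(Xtr.shape), svd_solver="full")
    Ztr = pca.fit_transform(Xtr)
    Zte = pca.transform(Xte)
    clf = spec.build().fit(Ztr, ytr)
    return clf.predict(Zte)


def decode(examples: TrialExamples, splits: list[CvSplit],
           spec: ClassifierSpec | None = None,
           condition: str = "") -> DecodingResult:
    """Run the PCA + linear-SVM pipeline over a list of splits."""
    spec = spec or ClassifierSpec()
    X = np.asarray(examples.features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    y = np.asarray(examples.labels)
    accs = []
    for split in splits:
        pred = _fit_split(X, y, split, spec)
        accs.append(float(np.mean(pred == y[split.test_indices])))
    scheme = splits[0].scheme if splits else ""
    if not condition:
        conds = np.unique(examples.conditions)
        condition = conds[0] if conds.size == 1 else "mixed"
    return DecodingResult(roi=examples.roi, condition=condition,
                          scheme=scheme, per_split_accuracy=np.asarray(accs))


class DecodingResults:
    """Fit output of :class:`CategoryDecoder`: accuracies and a summary."""

    def __init__(self, result: DecodingResult, splits: list[CvSplit],
                 spec: ClassifierSpec):
        self.result = result
        self.splits = splits
        self.spec = spec

    @property
    def per_split_accuracy(self) -> np.ndarray:
        return self.result.per_split_accuracy

    @property
    def mean_accuracy(self) -> float:
        return self.result.mean_accuracy

    @property
    def sem(self) -> float:
        a = self.per_split_accuracy
        return float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0

    def t_vs_chance(self, chance: float = 0.5) -> StatResult:
        """One-sample t of per-split accuracies against the chance level."""
        return one_sample_t(self.per_split_accuracy, chance, name="vs_chance")

    def to_frame(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame({
            "roi": r.roi, "condition": r.condition, "scheme": r.scheme,
            "split": np.arange(len(r.per_split_accuracy)),
            "accuracy": r.per_split_accuracy,
        })

    def summary(self) -> str:
        r = self.result
        lines = [
            "Category decoding results",
            "=" * 41,
            f"ROI:            {r.roi}",
            f"Condition:      {r.condition}",
            f"CV scheme:      {r.scheme} ({len(self.splits)} splits)",
            f"Classifier:     linear SVM ({self.spec.variant}, "
            f"C={self.spec.cost}, tol={self.spec.tolerance})",
            f"Mean accuracy:  {r.mean_accuracy:.4f}",
            f"SEM:            {self.sem:.4f}",
        ]
        return "\n".join(lines)


class CategoryDecoder:
    """Binary category decoder over one ROI's trial examples.

    Parameters
    ----------
    examples : TrialExamples for a single ROI (and usually one condition).
    spec : classifier configuration; defaults reproduce the standard setup.

    ``fit`` builds the requested cross-validation scheme and returns a
    :class:`DecodingResults` object.
    """

    def __init__(self, examples: TrialExamples,
                 spec: ClassifierSpec | None = None):
        self.examples = examples
        self.spec = spec or ClassifierSpec()

    def fit(self, scheme: str = "stratified", n_splits: int = 300,
            test_fraction: float = 0.2, n_pairs: int | None = None,
            seed=None) -> DecodingResults:
        ex = self.examples
        if scheme == "stratified":
            splits = make_stratified_splits(ex.labels, n_splits,
                                            test_fraction, seed)
        elif scheme == "word_pair":
            splits = make_word_pair_splits(ex.words, ex.labels, n_pairs, seed)
        elif scheme == "run":
            splits = make_run_splits(ex.run_ids)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        result = decode(ex, splits, self.spec)
        return DecodingResults(result, splits, self.spec)


def group_level_stats(accuracies: pd.DataFrame, chance: float = 0.5,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Group inference on per-subject mean accuracies.

    ``accuracies`` needs columns ``subject``, ``roi``, ``condition``,
    ``accuracy`` (one row per subject x ROI x condition).  Per ROI and
    condition a one-sample t against chance is run (FDR within condition
    across ROIs); per ROI a paired t contrasts deep - shallow (FDR across
    ROIs).  Returns a tidy table of :class:`semdepth.stats.StatResult` rows.
    """
    required = {"subject", "roi", "condition", "accuracy"}
    if not required.issubset(accuracies.columns):
        raise ValueError(f"accuracy table needs columns {sorted(required)}")
    n_subj = accuracies["subject"].nunique()
    if n_subj < 3:
        raise ValueError("group statistics require at least 3 subjects")
    rows = []
    for cond, sub in accuracies.groupby("condition"):
        family = []
        for roi, cell in sub.groupby("roi"):
            vals = cell.sort_values("subject")["accuracy"].to_numpy()
            family.append(one_sample_t(vals, chance, name=f"{roi}|{cond}"))
        attach_fdr(family, alpha=alpha)
        for r in family:
            roi = r.name.split("|")[0]
            rows.append({"analysis": "vs_chance", "roi": roi,
                         "condition": cond, **r.as_dict()})
    conds = set(accuracies["condition"].unique())
    if {"deep", "shallow"}.issubset(conds):
        wide = accuracies.pivot_table(index=["subject", "roi"],
                                      columns="condition",
                                      values="accuracy").reset_index()
        if wide[["deep", "shallow"]].isna().any().any():
            raise ValueError("mismatched subject sets between conditions")
        family = []
        for roi, cell in wide.groupby("roi"):
            cell = cell.sort_values("subject")
            family.append(paired_t(cell["deep"].to_numpy(),
                                   cell["shallow"].to_numpy(),
                                   name=str(roi)))
        attach_fdr(family, alpha=alpha)
        for r in family:
            rows.append({"analysis": "deep_vs_shallow", "roi": r.name,
                         "condition": "contrast", **r.as_dict()})
    return pd.DataFrame(rows)
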