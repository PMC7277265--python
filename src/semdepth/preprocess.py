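"""Run-wise normalization and trial-example extraction for ROI time series.

The pipeline mirrors standard event-related MVPA data preparation: invariant
voxels are dropped, each voxel's time series is linearly detrended and
z-scored within run, and per-trial examples are built by averaging the
volumes in a fixed post-onset window that tracks the haemodynamic lag
(volumes acquired 3.4-8.6 s after word onset; the classifier feature vector
averages the 3.4-6.8 s sub-interval).

Event onsets are expressed in seconds on the *post-discard* time grid: the
acquisition time of retained volume ``k`` is ``k * tr``.  Use
``shift_onsets_for_discard`` when events were logged against scanner start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BoldRun",
    "TrialExamples",
    "TrialVolumeSeries",
    "validate_events",
    "shift_onsets_for_discard",
    "discard_initial_volumes",
    "remove_invariant_voxels",
    "remove_invariant_voxels_dataset",
    "normalize_runs",
    "extract_trial_examples",
    "extract_trial_volume_series",
    "EXAMPLE_WINDOW_START_S",
    "CLASSIFIER_WINDOW_END_S",
    "EXAMPLE_WINDOW_N_VOLUMES",
]

# Post-onset averaging window: six volumes from 3.4 s; the classifier vector
# averages only those volumes acquired no later than 6.8 s after onset.
EXAMPLE_WINDOW_START_S = 3.4
CLASSIFIER_WINDOW_END_S = 6.8
EXAMPLE_WINDOW_N_VOLUMES = 6

EVENT_COLUMNS = ("onset", "duration", "word", "category", "condition",
                 "run_id", "is_catch")


@dataclass
class BoldRun:
    """One run's voxel x volume matrix for a single ROI.

    ``n_discarded`` counts leading dummy volumes still present in ``data``;
    after :func:`discard_initial_volumes` (or :func:`normalize_runs`) it is 0
    and volume ``k`` was acquired at ``k * tr`` seconds.
    """

    data: np.ndarray
    tr: float
    run_id: str
    roi_id: str
    n_discarded: int = 0
    condition: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BoldRun.data must be voxel x volume (2-D)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in run {self.run_id!r}")
        if self.data.shape[1] <= self.n_discarded:
            raise ValueError("volume count must exceed n_discarded")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialExamples:
    """Trial x voxel examples with labels; catch trials are excluded."""

    features: np.ndarray            # (n_trials, n_voxels) window mean
    volume_stack: list              # per trial (n_window_volumes, n_voxels)
    labels: np.ndarray              # category per trial
    words: np.ndarray
    run_ids: np.ndarray
    conditions: np.ndarray
    roi: str = ""
    dropped: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    def subset(self, mask) -> "TrialExamples":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return TrialExamples(
            features=self.features[idx],
            volume_stack=[self.volume_stack[i] for i in idx],
            labels=self.labels[idx], words=self.words[idx],
            run_ids=self.run_ids[idx], conditions=self.conditions[idx],
            roi=self.roi, dropped=list(self.dropped),
        )


@dataclass
class TrialVolumeSeries:
    """All volumes assigned to one trial (onset up to the next onset)."""

    data: np.ndarray                # (n_voxels, n_volumes_in_span)
    volume_indices: np.ndarray      # indices on the post-discard grid
    run_id: str
    word: str
    category: str
    condition: str | None
    onset: float
    is_catch: bool = False


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-table schema and ordering; returns the frame."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    onsets = events["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets must be strictly increasing within run")
    cat_by_word = events.loc[~events["is_catch"]].groupby("word")["category"].nunique()
    if (cat_by_word > 1).any():
        bad = cat_by_word[cat_by_word > 1].index.tolist()
        raise ValueError(f"inconsistent category for words: {bad}")
    return events


def shift_onsets_for_discard(events: pd.DataFrame, n_discard: int,
                             tr: float) -> pd.DataFrame:
    """Convert scanner-start onsets to the post-discard grid."""
    out = events.copy()
    out["onset"] = out["onset"] - n_discard * tr
    return out


def _varies(data: np.ndarray) -> np.ndarray:
    """Per-voxel flag: series is not constant (exact max > min)."""
    return data.max(axis=1) > data.min(axis=1)


def discard_initial_volumes(run: BoldRun) -> BoldRun:
    """Drop the leading dummy volumes flagged by ``n_discarded``."""
    if run.n_discarded == 0:
        return run
    return replace(run, data=run.data[:, run.n_discarded:], n_discarded=0)


def remove_invariant_voxels(run: BoldRun):
    """Drop voxels with zero sample variance over the run.

    Returns the reduced run and the retained voxel indices (for traceability
    back to the mask ordering).
    """
    if run.data.size == 0:
        raise ValueError("empty run")
    kept = np.flatnonzero(_varies(run.data))
    if kept.size == 0:
        raise ValueError(f"all voxels invariant in run {run.run_id!r} "
                         f"(ROI {run.roi_id!r})")
    return replace(run, data=run.data[kept]), kept


def remove_invariant_voxels_dataset(runs: list[BoldRun], per_run: bool = True):
    """Apply the invariant-voxel rule consistently across a run stack.

    With ``per_run=True`` (default) a voxel is removed from *every* run if it
    is invariant within *any single* run, so all runs keep an identical voxel
    set.  ``per_run=False`` instead tests variance on the stacked series.
    """
    if not runs:
        raise ValueError("no runs")
    n_vox = runs[0].n_voxels
    if any(r.n_voxels != n_vox for r in runs):
        raise ValueError("runs have mismatched voxel counts")
    if per_run:
        ok = np.ones(n_vox, dtype=bool)
        for r in runs:
            ok &= _varies(r.data)
    else:
        stacked = np.concatenate([r.data for r in runs], axis=1)
        ok = _varies(stacked)
    kept = np.flatnonzero(ok)
    if kept.size == 0:
        raise ValueError("all voxels invariant across the dataset")
    return [replace(r, data=r.data[kept]) for r in runs], kept


def normalize_runs(runs: list[BoldRun]):
    """Linear-detrend then z-score each voxel's series, run-wise.

    Leading dummy volumes are dropped first.  Detrending removes the
    least-squares line over volume index; the residuals are then centred and
    scaled to unit standard deviation.  A voxel whose residuals have zero
    variance (e.g. a pure linear trend) is set to all-zeros and reported in
    the returned warnings list rather than silently rescaled.

    Returns ``(normalized_runs, warnings)`` where each warning is a
    ``(run_id, roi_id, voxel_index)`` triple.
    """
    out, warnings = [], []
    for run in runs:
        run = discard_initial_volumes(run)
        x = run.data
        t = np.arange(x.shape[1], dtype=float)
        t_c = t - t.mean()
        denom = float(t_c @ t_c)
        slope = (x @ t_c) / denom
        resid = x - x.mean(axis=1, keepdims=True) - np.outer(slope, t_c)
        sd = resid.std(axis=1)
        flat = sd <= 1e-10 * (1.0 + np.abs(x).max(axis=1))
        sd_safe = np.where(flat, 1.0, sd)
        z = resid / sd_safe[:, None]
        z[flat] = 0.0
        for v in np.flatnonzero(flat):
            warnings.append((run.run_id, run.roi_id, int(v)))
        out.append(replace(run, data=z))
    return out, warnings


def _window_indices(onset: float, tr: float, n_volumes: int):
    """Six-volume example window and the classifier sub-window within it.

    The window holds the first six volumes acquired at or after
    ``onset + 3.4`` s; the classifier averages the subset acquired no later
    than ``onset + 6.8`` s (five volumes at TR 0.85 s).  Returns
    ``(window_idx, classifier_mask)`` or ``None`` when fewer than six volumes
    remain in the run.
    """
    eps = 1e-9
    i0 = math.ceil((onset + EXAMPLE_WINDOW_START_S) / tr - eps)
    i0 = max(i0, 0)
    idx = np.arange(i0, i0 + EXAMPLE_WINDOW_N_VOLUMES)
    if idx[-1] >= n_volumes:
        return None
    times = idx * tr
    cls_mask = times <= onset + CLASSIFIER_WINDOW_END_S + eps
    return idx, cls_mask


def extract_trial_examples(runs: list[BoldRun], events: list[pd.DataFrame],
                           vector: str = "classifier") -> TrialExamples:
    """Build trial x voxel examples from normalized runs of one ROI.

    Parameters
    ----------
    runs, events : parallel lists (one event table per run).
    vector : ``"classifier"`` averages the 3.4-6.8 s sub-window (default);
        ``"example"`` averages all six window volumes.

    Catch trials are excluded.  Trials whose window would run past the end of
    the run are dropped and listed in ``TrialExamples.dropped``.
    """
    if len(runs) != len(events):
        raise ValueError("runs and events must be parallel lists")
    if vector not in ("classifier", "example"):
        raise ValueError("vector must be 'classifier' or 'example'")
    feats, stacks, labels, words, run_ids, conds, dropped = \
        [], [], [], [], [], [], []
    roi = runs[0].roi_id if runs else ""
    for run, ev in zip(runs, events):
        if run.n_discarded:
            raise ValueError("normalize runs (discard dummies) before "
                             "extracting examples")
        validate_events(ev)
        for row in ev.itertuples(index=False):
            if row.is_catch:
                continue
            win = _window_indices(float(row.onset), run.tr, run.n_volumes)
            if win is None:
                dropped.append((run.run_id, row.word, float(row.onset)))
                continue
            idx, cls_mask = win
            block = run.data[:, idx].T           # (6, n_voxels)
            mean_mask = cls_mask if vector == "classifier" \
                else np.ones(len(idx), dtype=bool)
            feats.append(block[mean_mask].mean(axis=0))
            stacks.append(block)
            labels.append(row.category)
            words.append(row.word)
            run_ids.append(run.run_id)
            conds.append(row.condition)
    return TrialExamples(
        features=np.asarray(feats, dtype=float),
        volume_stack=stacks,
        labels=np.asarray(labels), words=np.asarray(words),
        run_ids=np.asarray(run_ids), conditions=np.asarray(conds),
        roi=roi, dropped=dropped,
    )


def extract_trial_volume_series(runs: list[BoldRun],
                                events: list[pd.DataFrame],
                                include_catch: bool = False
                                ) -> list[TrialVolumeSeries]:
    """Partition each run's volumes into per-trial spans.

    A trial owns the volumes acquired from its onset (inclusive) up to the
    next trial's onset (exclusive); the last trial runs to the end of the
    run.  Volumes before the first onset belong to no trial.  Concatenating
    the spans therefore reproduces the run's volume order with no volume
    assigned twice.  With ``include_catch=False`` (default) catch trials are
    not emitted and their volumes are absorbed by the preceding span.
    """
    if len(runs) != len(events):
        raise ValueError("runs and events must be parallel lists")
    out: list[TrialVolumeSeries] = []
    eps = 1e-9
    for run, ev in zip(runs, events):
        if run.n_discarded:
            raise ValueError("discard dummy volumes before extracting series")
        validate_events(ev)
        rows = [r for r in ev.itertuples(index=False)
                if include_catch or not r.is_catch]
        onsets = [float(r.onset) for r in rows]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("overlapping trial windows")
        for i, row in enumerate(rows):
            start = math.ceil(onsets[i] / run.tr - eps)
            stop = math.ceil(onsets[i + 1] / run.tr - eps) \
                if i + 1 < len(rows) else run.n_volumes
            idx = np.arange(max(start, 0), stop)
            out.append(TrialVolumeSeries(
                data=run.data[:, idx], volume_indices=idx,
                run_id=run.run_id, word=row.word, category=row.category,
                condition=row.condition, onset=onsets[i],
                is_catch=bool(row.is_catch),
            ))
    return out
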