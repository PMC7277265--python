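"""Convenience wrappers chaining preprocessing into the analysis stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import discriminability_timeseries, informational_connectivity
from .decoding import CategoryDecoder, ClassifierSpec
from .preprocess import (TrialExamples, extract_trial_examples,
                         normalize_runs, remove_invariant_voxels_dataset)

__all__ = [
    "preprocess_roi",
    "condition_examples",
    "decode_dataset",
    "ic_matrix_for_condition",
]


def preprocess_roi(runs):
    """Invariant-voxel removal (per-run rule) then run-wise normalization."""
    runs, kept = remove_invariant_voxels_dataset(runs)
    runs, warnings_ = normalize_runs(runs)
    return runs, kept, warnings_


def _select_condition(runs, events, condition):
    if condition is None:
        return runs, events
    sel = [(r, e) for r, e in zip(runs, events) if r.condition == condition]
    if not sel:
        raise ValueError(f"no runs with condition {condition!r}")
    return [r for r, _ in sel], [e for _, e in sel]


def condition_examples(runs, events, condition=None,
                       vector: str = "classifier") -> TrialExamples:
    """Preprocess one ROI's runs and extract examples for one condition."""
    runs, events = _select_condition(runs, events, condition)
    runs, _, _ = preprocess_roi(runs)
    return extract_trial_examples(runs, events, vector=vector)


def decode_dataset(runs_by_roi: dict, events: list, scheme: str = "stratified",
                   n_splits: int = 300, n_pairs: int | None = None,
                   seed=None, spec: ClassifierSpec | None = None,
                   conditions=("deep", "shallow")) -> pd.DataFrame:
    """Per-ROI, per-condition decoding; returns a tidy accuracy table."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rows = []
    for roi, runs in runs_by_roi.items():
        for cond in conditions:
            ex = condition_examples(runs, events, cond)
            res = CategoryDecoder(ex, spec).fit(
                scheme=scheme, n_splits=n_splits, n_pairs=n_pairs, seed=rng)
            rows.append({"roi": roi, "condition": cond, "scheme": scheme,
                         "accuracy": res.mean_accuracy,
                         "n_splits": len(res.splits)})
    return pd.DataFrame(rows)


def ic_matrix_for_condition(runs_by_roi: dict, events: list, condition: str,
                            spec: ClassifierSpec | None = None):
    """Discriminability series per ROI and their IC matrix for one condition."""
    series = []
    for roi, runs in runs_by_roi.items():
        sel_runs, sel_events = _select_condition(runs, events, condition)
        sel_runs, _, _ = preprocess_roi(sel_runs)
        series.append(discriminability_timeseries(sel_runs, sel_events,
                                                  spec, condition=condition))
    return series, informational_connectivity(series)
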