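"""Readers and writers: NIfTI BOLD/masks, BIDS-style events TSV, feature CSV.

A simulated dataset is written as one 4-D NIfTI per run whose voxel grid is
the ROIs' voxels stacked along the first axis (identity affine, documented
here), one binary 3-D mask per ROI on that stacked grid, one events TSV per
run (tab-delimited, UTF-8, '.' decimal), and a JSON sidecar carrying the
configuration and run metadata.  Feature matrices travel as CSV with the
word in the first column.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preprocess import BoldRun, validate_events
from .simulate import (FeatureMatrix, RoiMask, RoiSpec, SimulatedDataset,
                       SimulationConfig)

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_events",
    "read_events",
    "write_features",
    "read_features",
    "load_config",
    "save_config",
]

EVENTS_FLOAT_COLS = ("onset", "duration", "iti")


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    validate_events(events)
    events.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def read_events(path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t", encoding="utf-8")
    ev["is_catch"] = ev["is_catch"].astype(bool)
    try:
        return validate_events(ev)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_features(features: FeatureMatrix, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(features.matrix,
                      columns=[f"dim{i:03d}"
                               for i in range(features.matrix.shape[1])])
    df.insert(0, "word", features.words)
    df.to_csv(path, index=False)
    return path


def read_features(path, model_name: str | None = None,
                  family: str = "embedding") -> FeatureMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "word":
        raise ValueError(f"{path}: first column must be 'word'")
    return FeatureMatrix(
        model_name=model_name or Path(path).stem, family=family,
        matrix=df.iloc[:, 1:].to_numpy(dtype=float),
        words=df["word"].to_numpy())


def write_dataset(dataset: SimulatedDataset, outdir) -> Path:
    """Write a simulated dataset to ``outdir`` (NIfTI + TSV + JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    affine = np.eye(4)
    total_vox = sum(m.n_voxels for m in dataset.masks)
    roi_order = [m.name for m in dataset.masks]

    for m in dataset.masks:
        vol = np.zeros((total_vox, 1, 1), dtype=np.uint8)
        vol[m.offset:m.offset + m.n_voxels] = 1
        nib.save(nib.Nifti1Image(vol, affine),
                 outdir / f"mask_{m.name}.nii")

    n_runs = len(dataset.events)
    for i in range(n_runs):
        stacked = np.concatenate(
            [dataset.runs[name][i].data for name in roi_order], axis=0)
        img = nib.Nifti1Image(stacked[:, None, None, :], affine)
        img.header.set_zooms((1.0, 1.0, 1.0, cfg.tr))
        nib.save(img, outdir / f"bold_run{i:02d}.nii")
        write_events(dataset.events[i], outdir / f"events_run{i:02d}.tsv")

    meta = {
        "tr": cfg.tr, "n_discard": cfg.n_discard, "n_runs": n_runs,
        "condition_order": list(cfg.condition_order),
        "roi_order": roi_order,
        "rois": [{"name": m.name, "n_voxels": m.n_voxels,
                  "offset": m.offset} for m in dataset.masks],
        "seed": cfg.seed,
    }
    (outdir / "dataset.json").write_text(json.dumps(meta, indent=2))
    return outdir


def read_dataset(indir):
    """Read a dataset written by :func:`write_dataset`.

    Returns ``(runs_by_roi, events, masks)`` with voxels within each mask
    ordered by ascending linear index of the mask grid.
    """
    indir = Path(indir)
    meta = json.loads((indir / "dataset.json").read_text())
    masks = [RoiMask(r["name"], r["n_voxels"], r["offset"])
             for r in meta["rois"]]
    events, runs_by_roi = [], {m.name: [] for m in masks}
    mask_vols = {}
    for m in masks:
        vol = np.asarray(nib.load(indir / f"mask_{m.name}.nii").dataobj)
        mask_vols[m.name] = np.flatnonzero(vol.ravel(order="C") > 0)
    for i in range(meta["n_runs"]):
        ev = read_events(indir / f"events_run{i:02d}.tsv")
        events.append(ev)
        img = nib.load(indir / f"bold_run{i:02d}.nii")
        data = np.asarray(img.dataobj, dtype=float)
        flat = data.reshape(-1, data.shape[-1])
        cond = meta["condition_order"][i]
        for m in masks:
            runs_by_roi[m.name].append(BoldRun(
                data=flat[mask_vols[m.name]], tr=meta["tr"],
                run_id=f"run{i:02d}", roi_id=m.name,
                n_discarded=meta["n_discard"], condition=cond))
    return runs_by_roi, events, masks


def save_config(config: SimulationConfig, path) -> Path:
    path = Path(path)
    d = {
        "n_runs": config.n_runs, "trials_per_run": config.trials_per_run,
        "n_words_per_category": config.n_words_per_category,
        "tr": config.tr, "volumes_per_run": config.volumes_per_run,
        "n_discard": config.n_discard, "fixation_s": config.fixation_s,
        "blank1_s": config.blank1_s, "word_s": config.word_s,
        "blank2_s": config.blank2_s,
        "jitter_levels": [list(x) for x in config.jitter_levels],
        "max_catch_per_run": config.max_catch_per_run,
        "condition_order": list(config.condition_order),
        "roi_specs": [vars(r) for r in config.roi_specs],
        "coupling": [list(c) for c in config.coupling],
        "seed": config.seed, "spacing": config.spacing,
    }
    path.write_text(yaml.safe_dump(d))
    return path


def load_config(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "roi_specs" in d:
        d["roi_specs"] = [RoiSpec(**r) for r in d["roi_specs"]]
    if "jitter_levels" in d:
        d["jitter_levels"] = tuple(tuple(x) for x in d["jitter_levels"])
    if "condition_order" in d and d["condition_order"] is not None:
        d["condition_order"] = tuple(d["condition_order"])
    if "coupling" in d:
        d["coupling"] = [tuple(c) for c in d["coupling"]]
    return SimulationConfig(**d)
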