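"""Synthetic event-related ROI fMRI with known multivoxel ground truth.

Emulates a two-condition (deep vs shallow processing) visual-word experiment:
8 runs of 36 word trials (18 living / 18 non-living Spanish nouns), TR 0.85 s,
520 volumes per run with the first 9 discarded, pseudo-exponential inter-trial
jitter of 6-8 s, and up to two number-word catch trials per run.

Each ROI carries a centred category pattern and per-word deviation patterns.
The per-trial signal amplitude is ``gating * (condition_gain * category_pattern
+ word_gain * word_pattern)``, convolved with a canonical double-gamma HRF and
added to baseline, slow drift and white Gaussian noise.  The trial-to-trial
gating series can be correlated between ROIs (a Gaussian copula), which is the
coupling that informational-connectivity analysis is designed to detect while
leaving ROI-mean signals untouched (patterns have zero spatial mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr

from .preprocess import BoldRun

__all__ = [
    "LIVING_WORDS",
    "NONLIVING_WORDS",
    "CATCH_WORDS",
    "RoiSpec",
    "RoiMask",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "FeatureMatrix",
    "double_gamma_hrf",
    "draw_jitter",
    "generate_schedule",
    "generate_dataset",
    "generate_features",
    "expand_features_to_trials",
]

# The study's word pool (Spanish): 18 animal and 18 tool nouns.
LIVING_WORDS = (
    "tigre", "gallo", "perro", "oveja", "cerdo", "gorila", "burro", "yegua",
    "ardilla", "conejo", "gallina", "caballo", "ballena", "tortuga",
    "pantera", "camello", "elefante", "canguro",
)
NONLIVING_WORDS = (
    "llave", "lapiz", "tijera", "aguja", "pinza", "sierra", "clavo",
    "pincel", "alicate", "tuerca", "navaja", "cepillo", "taladro",
    "soplete", "tornillo", "cuchara", "martillo", "cuchillo",
)
CATCH_WORDS = ("cero", "uno", "tres")

DEFAULT_JITTER = ((6.0, 0.5), (6.5, 0.25), (7.0, 0.125),
                  (7.5, 0.0625), (8.0, 0.0625))


@dataclass
class RoiSpec:
    """Signal parameters for one simulated ROI.

    Gains are amplitudes (in noise-sd units when ``noise_sd=1``) applied to
    unit-variance voxel patterns; ``category_gain_deep``/``_shallow``
    parameterize the condition contrast, ``word_gain`` the word-specific
    (within-category) pattern.
    """

    name: str
    n_voxels: int = 50
    category_gain_deep: float = 1.0
    category_gain_shallow: float = 0.35
    word_gain: float = 0.5
    noise_sd: float = 1.0
    drift_amplitude: float = 1.0

    def validate(self):
        if self.n_voxels < 2:
            raise ValueError(f"ROI {self.name!r}: n_voxels must be >= 2")
        gains = (self.category_gain_deep, self.category_gain_shallow,
                 self.word_gain, self.drift_amplitude)
        if any((not np.isfinite(g)) or g < 0 for g in gains):
            raise ValueError(f"ROI {self.name!r}: gains must be finite and >= 0")
        if not (np.isfinite(self.noise_sd) and self.noise_sd > 0):
            raise ValueError(f"ROI {self.name!r}: noise_sd must be > 0")


@dataclass
class RoiMask:
    """Named voxel set; ``offset`` is its start on the stacked voxel axis."""

    name: str
    n_voxels: int
    offset: int = 0


def _default_rois():
    return [RoiSpec("IPL"), RoiSpec("MTL"), RoiSpec("FFG")]


@dataclass
class SimulationConfig:
    """Design parameters of the simulated experiment (defaults = the study).

    ``spacing`` selects the onset-to-onset rule: ``"compact"`` (default)
    reproduces the 10.75-12.75 s inter-word interval that fits the
    520-volume run (the 1 s word display overlaps the start of the 4 s
    task delay), while ``"component_sum"`` adds all component durations
    (11.75-13.75 s), which overshoots the scan length at full trial counts.
    """

    n_runs: int = 8
    trials_per_run: int = 36
    n_words_per_category: int = 18
    tr: float = 0.85
    volumes_per_run: int = 520
    n_discard: int = 9
    fixation_s: float = 0.25
    blank1_s: float = 0.5
    word_s: float = 1.0
    blank2_s: float = 4.0
    jitter_levels: tuple = DEFAULT_JITTER
    max_catch_per_run: int = 2
    condition_order: tuple | None = None
    roi_specs: list = field(default_factory=_default_rois)
    coupling: list = field(default_factory=list)
    seed: int = 0
    spacing: str = "compact"
    baseline: float = 100.0
    neural_duration_s: float = 5.0   # word + simulation delay drive the HRF
    drift_period_s: float = 120.0

    def __post_init__(self):
        if self.condition_order is None:
            self.condition_order = tuple(
                "deep" if i % 2 == 0 else "shallow" for i in range(self.n_runs)
            )
        self.validate()

    def validate(self):
        probs = [p for _, p in self.jitter_levels]
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("jitter probabilities must sum to 1")
        if self.trials_per_run != 2 * self.n_words_per_category:
            raise ValueError("trials_per_run must equal 2 * n_words_per_category")
        for d in (self.tr, self.fixation_s, self.blank1_s, self.word_s,
                  self.blank2_s):
            if d <= 0:
                raise ValueError("all durations must be positive")
        if len(self.condition_order) != self.n_runs:
            raise ValueError("condition_order must have one entry per run")
        counts = pd.Series(self.condition_order).value_counts()
        if counts.nunique() > 1:
            raise ValueError("condition_order must balance the conditions")
        if self.spacing not in ("compact", "component_sum"):
            raise ValueError("spacing must be 'compact' or 'component_sum'")
        names = [r.name for r in self.roi_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate ROI names")
        for r in self.roi_specs:
            r.validate()
        for entry in self.coupling:
            a, b = entry[0], entry[1]
            s = float(entry[2])
            if a not in names or b not in names:
                raise ValueError(f"coupling references unknown ROI: {(a, b)}")
            if not 0.0 <= s <= 1.0:
                raise ValueError("coupling strength must lie in [0, 1]")

    def word_pool(self):
        living = LIVING_WORDS[: self.n_words_per_category]
        nonliving = NONLIVING_WORDS[: self.n_words_per_category]
        if len(living) < self.n_words_per_category \
                or len(nonliving) < self.n_words_per_category:
            raise ValueError("word pool smaller than n_words_per_category")
        return living, nonliving

    @property
    def run_duration_s(self) -> float:
        return self.volumes_per_run * self.tr


@dataclass
class GroundTruth:
    """Planted quantities returned for recovery tests."""

    category_patterns: dict          # roi -> {category: (n_voxels,) centred}
    word_patterns: dict              # roi -> {word: (n_voxels,) centred}
    gating_series: dict              # roi -> list of per-run (n_trials,) in [0,1]
    coupling_pairs: list
    feature_map: np.ndarray | None = None


@dataclass
class SimulatedDataset:
    runs: dict                       # roi -> list[BoldRun] (one per run)
    events: list                     # one DataFrame per run
    masks: list                      # RoiMask, with stacked-axis offsets
    ground_truth: GroundTruth
    config: SimulationConfig


def double_gamma_hrf(tr: float, duration_s: float = 32.0,
                     oversampling: int = 1) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr / oversampling`` s.

    Positive gamma with delay 6, undershoot gamma with delay 16, ratio 1/6
    (unit dispersions); normalized to unit peak.
    """
    dt = tr / oversampling
    t = np.arange(0, duration_s, dt)
    h = sps.gamma.pdf(t, a=6.0) - sps.gamma.pdf(t, a=16.0) / 6.0
    return h / h.max()


def draw_jitter(n: int, rng: np.random.Generator,
                levels=DEFAULT_JITTER) -> np.ndarray:
    """Draw ``n`` inter-trial jitter durations from the discrete law."""
    values = np.array([v for v, _ in levels], dtype=float)
    probs = np.array([p for _, p in levels], dtype=float)
    return rng.choice(values, size=n, p=probs)


def generate_schedule(config: SimulationConfig, run_index: int,
                      seed=None) -> pd.DataFrame:
    """One run's randomized event table (one trial per word, plus catches).

    Onsets are word onsets in seconds on the post-discard grid.  Raises a
    ``ValueError`` naming the run if the drawn schedule cannot fit within
    ``volumes_per_run * tr``.
    """
    if run_index >= config.n_runs:
        raise ValueError("run_index out of range")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    living, nonliving = config.word_pool()
    words = list(living) + list(nonliving)
    categories = {w: "living" for w in living}
    categories.update({w: "nonliving" for w in nonliving})
    order = [words[i] for i in rng.permutation(len(words))]

    n_catch = int(rng.integers(0, config.max_catch_per_run + 1))
    catch_positions = sorted(
        rng.choice(len(order) + 1, size=n_catch, replace=False))
    for k, pos in enumerate(catch_positions):
        order.insert(pos + k, CATCH_WORDS[int(rng.integers(len(CATCH_WORDS)))])

    condition = config.condition_order[run_index]
    jitters = draw_jitter(len(order), rng, config.jitter_levels)
    pre_word = config.fixation_s + config.blank1_s
    if config.spacing == "component_sum":
        step_base = pre_word + config.word_s + config.blank2_s
    else:  # compact: word display counted inside the post-word delay
        step_base = pre_word + config.blank2_s

    rows, onset = [], pre_word
    for word, jit in zip(order, jitters):
        is_catch = word in CATCH_WORDS
        rows.append({
            "onset": onset, "duration": config.word_s,
            "trial_type": "catch" if is_catch else "word",
            "word": word,
            "category": "catch" if is_catch else categories[word],
            "condition": condition,
            "run_id": f"run{run_index:02d}",
            "is_catch": is_catch, "iti": float(jit),
        })
        onset += step_base + jit
    end_time = rows[-1]["onset"] + config.word_s + config.blank2_s
    if end_time > config.run_duration_s:
        raise ValueError(
            f"run {run_index}: schedule length {end_time:.1f}s exceeds run "
            f"duration {config.run_duration_s:.1f}s")
    return pd.DataFrame(rows)


def _latent_correlation(strength: float) -> float:
    # Gaussian-copula latent correlation giving Pearson ``strength`` between
    # the probability-transformed (uniform) gating series.
    return float(2.0 * np.sin(np.pi * strength / 6.0))


def _gating_series(config: SimulationConfig, events: list[pd.DataFrame],
                   rng: np.random.Generator) -> dict:
    rois = [r.name for r in config.roi_specs]
    latents = {
        roi: [rng.standard_normal(len(ev)) for ev in events] for roi in rois
    }
    for entry in config.coupling:
        a, b, s = entry[0], entry[1], float(entry[2])
        cond = entry[3] if len(entry) > 3 else None
        rho = _latent_correlation(s)
        for i in range(config.n_runs):
            if cond is not None and config.condition_order[i] != cond:
                continue
            za = latents[a][i]
            latents[b][i] = rho * za + np.sqrt(1.0 - rho ** 2) * latents[b][i]
    return {roi: [ndtr(z) for z in zs] for roi, zs in latents.items()}


def generate_dataset(config: SimulationConfig,
                     feature_map: np.ndarray | None = None
                     ) -> SimulatedDataset:
    """Generate per-ROI BOLD runs, event tables, masks and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    events = [generate_schedule(config, i, rng) for i in range(config.n_runs)]
    gating = _gating_series(config, events, rng)

    living, nonliving = config.word_pool()
    word_list = list(living) + list(nonliving)
    category_of = {w: ("living" if w in living else "nonliving")
                   for w in word_list}

    def centred(v):
        return v - v.mean()

    cat_patterns, word_patterns = {}, {}
    for spec in config.roi_specs:
        cat_patterns[spec.name] = {
            "living": centred(rng.standard_normal(spec.n_voxels)),
            "nonliving": centred(rng.standard_normal(spec.n_voxels)),
        }
        # Word patterns are independent deviations around the category
        # pattern; being i.i.d. they carry no category information in
        # expectation (a finite pool leaks a small chance class-mean).
        word_patterns[spec.name] = {
            w: centred(rng.standard_normal(spec.n_voxels)) for w in word_list
        }

    oversampling = 10
    dt = config.tr / oversampling
    hrf = double_gamma_hrf(config.tr, oversampling=oversampling)
    n_fine = int(np.ceil(config.run_duration_s / dt)) + hrf.size
    vol_times = np.arange(config.volumes_per_run) * config.tr
    discard_shift = config.n_discard * config.tr
    # Reference response of one isolated trial; regressors are scaled to
    # unit peak so gains are peak BOLD amplitudes (noise-sd units).
    n_box = max(int(round(config.neural_duration_s / dt)), 1)
    ref_peak = float(np.convolve(np.ones(n_box), hrf).max())

    runs: dict = {spec.name: [] for spec in config.roi_specs}
    for i, ev in enumerate(events):
        condition = config.condition_order[i]
        onsets = ev["onset"].to_numpy(dtype=float) + discard_shift
        # Per-trial HRF-convolved regressors sampled at the volume grid.
        regs = np.zeros((len(ev), config.volumes_per_run))
        for t_idx, onset in enumerate(onsets):
            fine = np.zeros(n_fine)
            a = int(round(onset / dt))
            b = min(int(round((onset + config.neural_duration_s) / dt)), n_fine)
            fine[a:b] = 1.0
            conv = np.convolve(fine, hrf)[:n_fine] / ref_peak
            regs[t_idx] = np.interp(vol_times, np.arange(n_fine) * dt, conv)
        for spec in config.roi_specs:
            g = gating[spec.name][i]
            gain = spec.category_gain_deep if condition == "deep" \
                else spec.category_gain_shallow
            amps = np.zeros((len(ev), spec.n_voxels))
            for t_idx, row in enumerate(ev.itertuples(index=False)):
                if row.is_catch:
                    continue
                amps[t_idx] = g[t_idx] * (
                    gain * cat_patterns[spec.name][row.category]
                    + spec.word_gain * word_patterns[spec.name][row.word])
            signal = amps.T @ regs                       # (voxels, volumes)
            t_norm = (vol_times / vol_times[-1]) - 0.5
            slope = rng.normal(0.0, spec.drift_amplitude, spec.n_voxels)
            phase = rng.uniform(0, 2 * np.pi, spec.n_voxels)
            drift = (np.outer(slope, t_norm)
                     + spec.drift_amplitude
                     * np.cos(np.outer(np.ones(spec.n_voxels),
                                       2 * np.pi * vol_times
                                       / config.drift_period_s)
                              + phase[:, None]))
            noise = rng.normal(0.0, spec.noise_sd,
                               (spec.n_voxels, config.volumes_per_run))
            data = config.baseline + drift + noise + signal
            runs[spec.name].append(BoldRun(
                data=data, tr=config.tr, run_id=f"run{i:02d}",
                roi_id=spec.name, n_discarded=config.n_discard,
                condition=condition))

    masks, offset = [], 0
    for spec in config.roi_specs:
        masks.append(RoiMask(spec.name, spec.n_voxels, offset))
        offset += spec.n_voxels
    truth = GroundTruth(
        category_patterns=cat_patterns, word_patterns=word_patterns,
        gating_series=gating, coupling_pairs=list(config.coupling),
        feature_map=feature_map)
    return SimulatedDataset(runs=runs, events=events, masks=masks,
                            ground_truth=truth, config=config)


@dataclass
class FeatureMatrix:
    """Word (or trial) x dimension representation of one stimulus model."""

    model_name: str
    family: str                      # "embedding" or "vision"
    matrix: np.ndarray
    words: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.words = np.asarray(self.words)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite feature values")
        if self.matrix.shape[0] != self.words.size:
            raise ValueError("one row per word required")


def generate_features(word_list, n_dims: int = 300, n_models: int = 2,
                      voxel_target: RoiSpec | None = None,
                      fidelity: float = 1.0, seed=None,
                      family: str = "embedding"):
    """Synthetic word-feature matrices sharing a latent structure.

    Each model's matrix is ``fidelity * latent + (1 - fidelity) * noise``
    where the latent structure carries a planted category separation
    (first half of ``word_list`` vs second half).  When ``voxel_target`` is
    given, a random linear map from the first model's feature space into
    that ROI's voxels is returned so encoding recovery is testable.

    Returns ``(feature_matrices, feature_map)``.
    """
    words = np.asarray(list(word_list))
    if words.size != np.unique(words).size:
        raise ValueError("duplicate words in word_list")
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_words = words.size
    half = n_words // 2
    category_axis = rng.standard_normal(n_dims)
    latent = rng.standard_normal((n_words, n_dims))
    latent[:half] += category_axis
    latent[half:] -= category_axis
    mats = []
    for m in range(n_models):
        noise = rng.standard_normal((n_words, n_dims))
        mats.append(FeatureMatrix(
            model_name=f"{family}_{m}", family=family,
            matrix=fidelity * latent + (1.0 - fidelity) * noise,
            words=words))
    feature_map = None
    if voxel_target is not None:
        feature_map = rng.standard_normal((n_dims, voxel_target.n_voxels)) \
            / np.sqrt(n_dims)
    return mats, feature_map


def expand_features_to_trials(features: FeatureMatrix,
                              trial_words) -> FeatureMatrix:
    """Repeat word rows to align one feature row with each trial."""
    lookup = {w: i for i, w in enumerate(features.words)}
    try:
        idx = np.array([lookup[w] for w in trial_words])
    except KeyError as err:
        raise ValueError(f"trial word missing from feature matrix: {err}")
    return FeatureMatrix(features.model_name, features.family,
                         features.matrix[idx], np.asarray(list(trial_words)))
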