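"""Hippocampal multivoxel decoding of stimulus locations.

Voxel time courses are Savitzky-Golay filtered (window 5 TRs, order 3) and
z-scored per voxel per run; trial features average volumes in a trial-locked
window (3-13.5 s for localizer blocks, 3-6 s for main-task events).  An
8-class multinomial logistic decoder (L2, C = 1) trained on the localizer
yields per-trial class probabilities ("classifier evidence"); the
successor/predecessor contrast subtracts the mean control-location evidence
and splits the sequence-location evidence by temporal-distance sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import savgol_filter
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from . import geometry, hemo
from .geometry import SequenceSpec
from .synth import VoxelTimeSeries

SAVGOL_WINDOW = 5
SAVGOL_ORDER = 3
LOCALIZER_WINDOW = (3.0, 13.5)
MAIN_TASK_WINDOW = (3.0, 6.0)


@dataclass
class PreprocessedSeries:
    values: np.ndarray            # voxels x volumes
    tr: float
    run_volumes: list[int]
    filter_window: int = SAVGOL_WINDOW
    filter_order: int = SAVGOL_ORDER

    def run_slices(self):
        edges = np.concatenate([[0], np.cumsum(self.run_volumes)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class TrialSamples:
    features: np.ndarray          # trials x voxels
    labels: np.ndarray            # stimulus location index per trial
    window: tuple[float, float]


def preprocess(ts: VoxelTimeSeries, window: int = SAVGOL_WINDOW,
               order: int = SAVGOL_ORDER) -> PreprocessedSeries:
    """Per-run Savitzky-Golay smoothing (nearest-edge padding) and per-voxel
    per-run z-scoring; constant voxels map to zero with a warning."""
    out = np.empty_like(ts.values, dtype=float)
    edges = np.concatenate([[0], np.cumsum(ts.run_volumes)])
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < window:
            raise ValueError("run shorter than the filter window")
        block = savgol_filter(ts.values[:, a:b], window, order, axis=1,
                              mode="nearest")
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=0, keepdims=True)
        flat = (sd[:, 0] == 0)
        if np.any(flat):
            warnings.warn(f"{int(flat.sum())} constant voxel(s) set to zero",
                          RuntimeWarning)
            sd[flat] = 1.0
        out[:, a:b] = (block - mean) / sd
        out[flat, a:b] = 0.0
    return PreprocessedSeries(values=out, tr=ts.tr,
                              run_volumes=list(ts.run_volumes))


def extract_trial_samples(ps: PreprocessedSeries, onsets, labels,
                          window: tuple[float, float],
                          run_index: np.ndarray | None = None) -> TrialSamples:
    """Average volumes whose trial-locked times fall in ``window`` (inclusive).

    ``onsets`` are within-run times; ``run_index`` assigns each trial to a run
    (all trials in run 0 when omitted).
    """
    start, end = window
    if not 0 <= start <= end:
        raise ValueError("need 0 <= start <= end")
    onsets = np.asarray(onsets, float)
    labels = np.asarray(labels)
    if run_index is None:
        run_index = np.zeros(onsets.size, dtype=int)
    edges = np.concatenate([[0], np.cumsum(ps.run_volumes)])
    rows = []
    for onset, run in zip(onsets, run_index):
        nvol = ps.run_volumes[run]
        times = np.arange(nvol) * ps.tr - onset
        sel = (times >= start - 1e-9) & (times <= end + 1e-9)
        if not np.any(sel):
            raise ValueError(f"window {window} contains no volume for a trial "
                             f"at {onset:.2f} s")
        block = ps.values[:, edges[run]:edges[run + 1]]
        rows.append(block[:, sel].mean(axis=1))
    return TrialSamples(features=np.asarray(rows), labels=labels,
                        window=(start, end))


def _make_decoder() -> LogisticRegression:
    # sklearn's default penalty is the L2 ridge; C = 1 is the stated strength
    return LogisticRegression(C=1.0, max_iter=2000)


def train_decoder(samples: TrialSamples) -> LogisticRegression:
    """Multinomial logistic decoder, L2 penalty, inverse strength C = 1."""
    if np.unique(samples.labels).size < 2:
        raise ValueError("need at least two classes to train")
    clf = _make_decoder()
    clf.fit(samples.features, samples.labels)
    return clf


def loo_cross_validate(samples: TrialSamples) -> float:
    """Leave-one-out decoding accuracy in [0, 1]."""
    hits = []
    for tr_idx, te_idx in LeaveOneOut().split(samples.features):
        clf = _make_decoder()
        clf.fit(samples.features[tr_idx], samples.labels[tr_idx])
        hits.append(clf.predict(samples.features[te_idx])[0]
                    == samples.labels[te_idx][0])
    return float(np.mean(hits))


def evidence(model: LogisticRegression, samples: TrialSamples) -> np.ndarray:
    """Per-trial class probabilities (trials x 8), columns in class order."""
    if samples.features.shape[1] != model.coef_.shape[1]:
        raise ValueError("feature dimension does not match the decoder")
    probs = model.predict_proba(samples.features)
    full = np.zeros((probs.shape[0], 8))
    full[:, np.asarray(model.classes_, int)] = probs
    return full


def crossvalidated_evidence(samples: TrialSamples, n_folds: int = 8,
                            seed: int = 0) -> np.ndarray:
    """Within-set evidence from stratified K-fold cross-validation."""
    out = np.zeros((samples.features.shape[0], 8))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr_idx, te_idx in skf.split(samples.features, samples.labels):
        clf = _make_decoder()
        clf.fit(samples.features[tr_idx], samples.labels[tr_idx])
        probs = clf.predict_proba(samples.features[te_idx])
        out[np.ix_(te_idx, np.asarray(clf.classes_, int))] = probs
    return out


def control_subtracted_sequence_evidence(probs: np.ndarray,
                                         spec: SequenceSpec) -> np.ndarray:
    """Per-trial evidence at the four sequence locations minus the mean
    evidence over the four control locations (trials x 4, sequence order)."""
    seq = list(spec.sequence_indices)
    ctl = list(spec.control_indices)
    return probs[:, seq] - probs[:, ctl].mean(axis=1, keepdims=True)


def evidence_contrast(probs: np.ndarray, trial_positions,
                      spec: SequenceSpec) -> tuple[float, float]:
    """Successor and predecessor mean evidence over partial trials.

    ``trial_positions`` gives each trial's shown sequence position (0..3).
    """
    adj = control_subtracted_sequence_evidence(probs, spec)
    succ, pred = [], []
    for row, s in zip(adj, np.asarray(trial_positions, int)):
        for j in range(4):
            if j > s:
                succ.append(row[j])
            elif j < s:
                pred.append(row[j])
    return float(np.mean(succ)), float(np.mean(pred))


def partial_trial_info(design) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Onsets, run indices, and shown sequence positions of partial trials."""
    onsets, runs, positions = [], [], []
    for r, trials in enumerate(design.runs):
        for trial in trials:
            if trial.trial_type != "full":
                onsets.append(trial.onset)
                runs.append(r)
                positions.append(geometry.PARTIAL_TYPES.index(trial.trial_type))
    return np.asarray(onsets), np.asarray(runs, int), np.asarray(positions, int)


def time_resolved_evidence(model: LogisticRegression, ps: PreprocessedSeries,
                           design, spec: SequenceSpec,
                           max_offset: float = 13.5) -> tuple[np.ndarray, np.ndarray]:
    """Successor-minus-predecessor evidence at each volume offset 0..13.5 s,
    using the localizer-trained decoder on single volumes of partial trials.

    For each offset the volume nearest ``onset + offset`` is used; trials
    without a full set of post-onset volumes are dropped once, so every
    offset sees the same trials.
    """
    onsets, runs, positions = partial_trial_info(design)
    offsets = np.arange(0.0, max_offset + 1e-9, ps.tr)
    edges = np.concatenate([[0], np.cumsum(ps.run_volumes)])
    keep = [i for i in range(onsets.size)
            if int(round((onsets[i] + max_offset) / ps.tr))
            < ps.run_volumes[runs[i]]]
    onsets, runs, positions = onsets[keep], runs[keep], positions[keep]
    diffs = []
    for off in offsets:
        vols = np.round((onsets + off) / ps.tr).astype(int) + edges[runs]
        feats = ps.values[:, vols].T
        samples = TrialSamples(features=feats, labels=positions,
                               window=(float(off), float(off)))
        probs = evidence(model, samples)
        succ, pred = evidence_contrast(probs, positions, spec)
        diffs.append(succ - pred)
    return offsets, np.asarray(diffs)


def fit_hrf_peak(offsets, timecourse, latency_bounds: tuple[float, float] = (-2.0, 8.0),
                 hrf_kind: str = "double") -> float | None:
    """Time-to-peak of a scaled, shifted canonical HRF fitted by least squares.

    Returns None ("no transient") when the best-fitting amplitude is not
    positive.  The peak is the fitted latency plus the HRF's own dense-grid
    argmax, so the estimate is shift-equivariant and scale-invariant.
    """
    t = np.asarray(offsets, float)
    y = np.asarray(timecourse, float)
    if t.size != y.size or t.size < 5:
        raise ValueError("need matched offsets/values with at least 5 points")

    def amp_for(lat: float) -> float:
        basis = hemo.canonical_hrf(np.clip(t - lat, 0.0, None), hrf_kind)
        basis[t - lat < 0] = 0.0
        denom = float(basis @ basis)
        return float(basis @ y) / denom if denom > 0 else 0.0

    def loss(lat: float) -> float:
        basis = hemo.canonical_hrf(np.clip(t - lat, 0.0, None), hrf_kind)
        basis[t - lat < 0] = 0.0
        a = amp_for(lat)
        return float(np.sum((a * basis - y) ** 2))

    grid = np.arange(latency_bounds[0], latency_bounds[1] + 1e-9, 0.05)
    lat0 = grid[int(np.argmin([loss(g) for g in grid]))]
    res = minimize_scalar(loss, bounds=(max(latency_bounds[0], lat0 - 0.05),
                                        min(latency_bounds[1], lat0 + 0.05)),
                          method="bounded", options={"xatol": 1e-4})
    lat = float(res.x) if res.fun <= loss(lat0) else float(lat0)
    if amp_for(lat) <= 0:
        return None
    return lat + hemo.hrf_peak_time(hrf_kind)
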