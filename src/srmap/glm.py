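"""GLM beta estimation, voxel selection, control subtraction, and the
successor/predecessor amplitude analysis.

The design matrix convolves condition events (impulses for brief dots,
boxcars for localizer blocks) with a single-gamma HRF basis on the same fine
grid the simulator uses; nuisance columns pass through unconvolved.  Betas are
ordinary least squares; contrast t statistics are mapped to z through the
normal quantile map.  The preregistered selection keeps the 25 most selective
voxels per location (one-vs-rest contrast z), drops voxels selective for more
than one location, and trims all sets to a common size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import geometry, hemo
from .geometry import SequenceSpec
from .synth import VoxelTimeSeries


@dataclass
class DesignMatrix:
    values: np.ndarray            # volumes x regressors
    names: list[str]
    tr: float

    @property
    def n_conditions(self) -> int:
        return sum(not n.startswith("nuisance") for n in self.names)


@dataclass
class BetaEstimates:
    betas: np.ndarray             # condition x voxel
    condition_names: list[str]
    tstats: dict[str, np.ndarray]
    zstats: dict[str, np.ndarray]
    residual_variance: np.ndarray


def build_design_matrix(events, n_volumes: int, tr: float = geometry.TR,
                        hrf_kind: str = "single",
                        nuisance: np.ndarray | None = None) -> DesignMatrix:
    """Convolved condition regressors sampled at volume times.

    ``events`` maps condition name -> list of (onset_s, duration_s); duration
    0 means an impulse.  Conditions with no events are rejected, as are events
    beyond the run end.
    """
    total = n_volumes * tr + hemo.KERNEL_LENGTH
    run_end = n_volumes * tr
    columns, names = [], []
    for name, evs in events.items():
        if len(evs) == 0:
            raise ValueError(f"condition {name!r} has no events")
        onsets = [e[0] for e in evs]
        durations = [e[1] for e in evs]
        if max(onsets) >= run_end:
            raise ValueError(f"condition {name!r} has events past the run end")
        fine = hemo.event_signal(onsets, [1.0] * len(evs), durations, total,
                                 kind=hrf_kind)
        columns.append(hemo.sample_at_volumes(fine, n_volumes, tr))
        names.append(name)
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, float))
        if nuisance.shape[0] != n_volumes:
            nuisance = nuisance.T
        for k in range(nuisance.shape[1]):
            columns.append(nuisance[:, k])
            names.append(f"nuisance_{k}")
    return DesignMatrix(values=np.column_stack(columns), names=names, tr=tr)


def main_task_events(run_trials) -> dict[str, list[tuple[float, float]]]:
    """Condition events for one main-task run: 4 partial types + full."""
    events: dict[str, list[tuple[float, float]]] = {
        t: [] for t in geometry.PARTIAL_TYPES}
    events["full"] = []
    for trial in run_trials:
        if trial.trial_type == "full":
            events["full"].append((trial.onset, 0.0))
        else:
            events[trial.trial_type].append((trial.onset, 0.0))
    return events


def localizer_events(schedule) -> dict[str, list[tuple[float, float]]]:
    """Condition events for the localizer: one boxcar condition per location."""
    events: dict[str, list[tuple[float, float]]] = {
        f"loc_{k}": [] for k in range(8)}
    for block in schedule:
        if not block.rest:
            events[f"loc_{block.location}"].append(
                (block.onset, block.duration))
    return events


def _z_from_t(t: np.ndarray, df: int) -> np.ndarray:
    """Normal quantile map of the t CDF, numerically safe in the tails."""
    t = np.asarray(t, float)
    sf = np.clip(sps.t.sf(np.abs(t), df), 1e-300, 1.0)
    return np.sign(t) * np.abs(sps.norm.isf(sf))


def fit_glm(ts, X: DesignMatrix,
            contrasts: dict[str, np.ndarray] | None = None) -> BetaEstimates:
    """Voxel-wise ordinary least squares with optional contrast t/z maps."""
    Y = ts.values.T if isinstance(ts, VoxelTimeSeries) else np.asarray(ts, float).T
    M = X.values
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # name one column involved in the deficiency for the error message
        _, R = np.linalg.qr(M)
        bad = [X.names[i] for i in range(M.shape[1]) if abs(R[i, i]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient (columns: {bad})")
    n, p = M.shape
    gram_inv = np.linalg.inv(M.T @ M)
    betas = gram_inv @ M.T @ Y                 # p x voxels
    resid = Y - M @ betas
    dof = n - p
    sigma2 = np.sum(resid ** 2, axis=0) / dof  # per voxel
    tstats, zstats = {}, {}
    if contrasts:
        for name, c in contrasts.items():
            c = np.asarray(c, float)
            se = np.sqrt(sigma2 * float(c @ gram_inv @ c))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, (c @ betas) / se, 0.0)
            tstats[name] = t
            zstats[name] = _z_from_t(t, dof)
    return BetaEstimates(betas=betas, condition_names=list(X.names),
                         tstats=tstats, zstats=zstats,
                         residual_variance=sigma2)


def one_vs_rest_contrasts(names: list[str], prefix: str = "loc_") -> dict[str, np.ndarray]:
    """One-vs-all-other-locations contrast vectors over the named columns."""
    cond_idx = [i for i, n in enumerate(names) if n.startswith(prefix)]
    out = {}
    for i in cond_idx:
        c = np.zeros(len(names))
        c[i] = 1.0
        for j in cond_idx:
            if j != i:
                c[j] = -1.0 / (len(cond_idx) - 1)
        out[names[i]] = c
    return out


def select_voxels(zstats: dict[str, np.ndarray], n_top: int = 25,
                  prefix: str = "loc_") -> dict[int, np.ndarray]:
    """Preregistered selection: top-``n_top`` z per location, overlap removal,
    then trimming (dropping lowest-z voxels) to a common set size."""
    locations = sorted(int(k[len(prefix):]) for k in zstats)
    tops = {}
    for loc in locations:
        z = zstats[f"{prefix}{loc}"]
        k = min(n_top, z.size)
        order = np.argsort(z)[::-1][:k]
        tops[loc] = order
    counts = np.zeros(next(iter(zstats.values())).size, dtype=int)
    for order in tops.values():
        counts[order] += 1
    kept = {loc: np.array([v for v in tops[loc] if counts[v] == 1], dtype=int)
            for loc in locations}
    min_size = min(len(v) for v in kept.values())
    if min_size == 0:
        raise ValueError("a location was left with no selective voxels")
    out = {}
    for loc in locations:
        z = zstats[f"{prefix}{loc}"]
        vox = kept[loc]
        order = np.argsort(z[vox])[::-1][:min_size]
        out[loc] = np.sort(vox[order])
    return out


def roi_mean_betas(betas: BetaEstimates, voxel_sets: dict[int, np.ndarray],
                   conditions: list[str]) -> np.ndarray:
    """Condition x location matrix of ROI-mean betas."""
    out = np.zeros((len(conditions), len(voxel_sets)))
    for ci, cond in enumerate(conditions):
        row = betas.betas[betas.condition_names.index(cond)]
        for li, loc in enumerate(sorted(voxel_sets)):
            out[ci, li] = float(np.mean(row[voxel_sets[loc]]))
    return out


def control_subtract(cond_by_location: np.ndarray,
                     spec: SequenceSpec) -> np.ndarray:
    """4x4 activity profile: sequence-location betas minus the per-condition
    mean over the four control locations.

    ``cond_by_location`` holds one row per partial-trial condition (A..D) and
    one column per stimulus location (0..7).
    """
    arr = np.asarray(cond_by_location, float)
    if arr.shape != (4, 8) or not np.all(np.isfinite(arr)):
        raise ValueError("need finite betas for 4 partial conditions x 8 locations")
    seq = list(spec.sequence_indices)
    ctl = list(spec.control_indices)
    profile = arr[:, seq] - arr[:, ctl].mean(axis=1, keepdims=True)
    return profile


def successor_predecessor_average(profile: np.ndarray
                                  ) -> tuple[float, float, dict[int, float]]:
    """Mean off-diagonal activity split by temporal distance sign, plus
    per-lag means over lags -3..+3 (excluding 0)."""
    profile = np.asarray(profile, float)
    if profile.shape != (4, 4):
        raise ValueError("profile must be 4x4")
    succ, pred, by_lag = [], [], {}
    for lag in range(-3, 4):
        if lag == 0:
            continue
        cells = [profile[s, s + lag] for s in range(4) if 0 <= s + lag < 4]
        by_lag[lag] = float(np.mean(cells))
        (succ if lag > 0 else pred).extend(cells)
    return float(np.mean(succ)), float(np.mean(pred)), by_lag


def activity_profile(subject, n_top: int | None = None,
                     use_true_labels: bool = False) -> np.ndarray:
    """Full V1 pathway for one synthetic subject: localizer voxel selection,
    per-run main-task GLM, run-averaged ROI betas, control subtraction.

    ``n_top`` defaults to the simulated subpopulation size (25 in the original
    selection rule, which presumes thousands of candidate voxels)."""
    design = subject.design
    v1_main = subject.main["V1"]
    if n_top is None:
        n_top = subject.truth.voxels_per_location
    if use_true_labels:
        labels = v1_main.preferred_location
        voxel_sets = {loc: np.flatnonzero(labels == loc) for loc in range(8)}
    else:
        loc_ts = subject.localizer["V1"]
        events = localizer_events(design.localizer)
        X = build_design_matrix(events, loc_ts.values.shape[1], tr=loc_ts.tr)
        fit = fit_glm(loc_ts, X, one_vs_rest_contrasts(X.names))
        voxel_sets = select_voxels(fit.zstats, n_top=n_top)
    conditions = list(geometry.PARTIAL_TYPES)
    run_betas = []
    for r, sl in enumerate(v1_main.run_slices()):
        events = main_task_events(design.runs[r])
        nvol = v1_main.run_volumes[r]
        X = build_design_matrix(events, nvol, tr=design.tr)
        fit = fit_glm(v1_main.values[:, sl], X)
        run_betas.append(roi_mean_betas(fit, voxel_sets, conditions))
    return control_subtract(np.mean(run_betas, axis=0), subject.spec)
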