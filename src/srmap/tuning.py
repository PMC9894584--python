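"""Localizer coactivation (tuning) analysis over the four sequence locations.

Stimulating one learned sequence location during the localizer may coactivate
the others.  Four candidate tuning patterns for the resulting 4x4 evidence
matrix are compared: linear decay in temporal distance |lag| (slope +
intercept), linear decay in spatial chord distance (slope + intercept), a
forward-only SR decay (scale * gamma^lag), and a no-coactivation baseline
(one diagonal amplitude).  The constrained sequence geometry makes temporal
and spatial tuning provably distinguishable: the temporally adjacent pair A-B
is the spatially most distant one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import geometry, sr_models
from . import stats as group_stats
from .geometry import SequenceSpec, StimulusLayout

TUNING_MODELS = ("temporal", "spatial", "SR", "H0")


@dataclass
class TuningFitResult:
    model: str
    params: dict
    rmse: float
    bic: float
    k_params: int


def build_coactivation(probs: np.ndarray, stim_locations,
                       spec: SequenceSpec) -> np.ndarray:
    """4x4 coactivation matrix: cell (s, l) is the mean classifier evidence
    for sequence location l on localizer trials stimulating sequence item s,
    after subtracting each trial's mean control-location evidence.

    The control-location baseline removes the uncertainty floor the softmax
    spreads over all classes; without it the no-coactivation null could never
    fit evidence data, which live on the probability simplex.  Under uniform
    evidence every cell is therefore 0, and a perfect decoder yields an
    identity-like matrix.

    ``probs`` is trials x 8 evidence; ``stim_locations`` the stimulated
    location index per trial.  Trials at control locations are ignored.
    """
    probs = np.asarray(probs, float)
    stim = np.asarray(stim_locations, int)
    seq = list(spec.sequence_indices)
    ctl = list(spec.control_indices)
    adjusted = probs[:, seq] - probs[:, ctl].mean(axis=1, keepdims=True)
    out = np.full((4, 4), np.nan)
    for s_pos, s_loc in enumerate(seq):
        rows = adjusted[stim == s_loc]
        if rows.size == 0:
            raise ValueError(f"no localizer trials for sequence item {s_pos}")
        out[s_pos] = rows.mean(axis=0)
    return out


def _design(model: str, spec: SequenceSpec, layout: StimulusLayout):
    """Cellwise covariates of each tuning model over the 4x4 matrix."""
    lag = -np.subtract.outer(np.arange(4), np.arange(4))  # lag[i, j] = j - i
    if model == "temporal":
        return np.abs(lag).astype(float)
    if model == "spatial":
        d = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                d[i, j] = geometry.chord_distance(
                    layout, spec.sequence_indices[i], spec.sequence_indices[j])
        return d
    raise ValueError(model)


def tuning_predictions(model: str, spec: SequenceSpec, layout: StimulusLayout,
                       params: dict) -> np.ndarray:
    """Predicted 4x4 coactivation matrix for one tuning model."""
    if model == "temporal":
        return params["intercept"] + params["slope"] * _design(model, spec, layout)
    if model == "spatial":
        return params["intercept"] + params["slope"] * _design(model, spec, layout)
    if model == "SR":
        lag = -np.subtract.outer(np.arange(4), np.arange(4))  # lag[i, j] = j - i
        pred = np.where(lag >= 0, params["gamma"] ** np.clip(lag, 0, None), 0.0)
        return params["scale"] * pred
    if model == "H0":
        return params["amplitude"] * np.eye(4)
    raise ValueError(f"unknown tuning model {model!r}")


def fit_tuning(coact: np.ndarray, model: str, spec: SequenceSpec,
               layout: StimulusLayout | None = None) -> TuningFitResult:
    """Least-squares fit of one tuning model over all 16 cells."""
    if layout is None:
        layout = geometry.build_layout()
    y = np.asarray(coact, float)
    if y.shape != (4, 4) or not np.all(np.isfinite(y)):
        raise ValueError("coactivation matrix must be a finite 4x4 matrix")
    n = y.size
    if model in ("temporal", "spatial"):
        x = _design(model, spec, layout).ravel()
        X = np.column_stack([np.ones(n), x])
        coef, *_ = np.linalg.lstsq(X, y.ravel(), rcond=None)
        params = {"intercept": float(coef[0]), "slope": float(coef[1])}
        k = 2
    elif model == "SR":
        lag = -np.subtract.outer(np.arange(4), np.arange(4))
        mask = lag >= 0

        def loss(g: float) -> float:
            basis = np.where(mask, g ** np.clip(lag, 0, None), 0.0).ravel()
            denom = float(basis @ basis)
            a = float(basis @ y.ravel()) / denom if denom > 0 else 0.0
            return float(np.sum((a * basis - y.ravel()) ** 2))

        grid = np.arange(0.0, 1.0 + 1e-12, 0.01)
        g0 = grid[int(np.argmin([loss(g) for g in grid]))]
        res = minimize_scalar(loss, bounds=(max(0.0, g0 - 0.01),
                                            min(1.0, g0 + 0.01)),
                              method="bounded", options={"xatol": 1e-7})
        g = float(res.x) if res.fun <= loss(g0) else float(g0)
        basis = np.where(mask, g ** np.clip(lag, 0, None), 0.0).ravel()
        a = float(basis @ y.ravel()) / float(basis @ basis)
        params = {"gamma": g, "scale": a}
        k = 2
    elif model == "H0":
        params = {"amplitude": float(np.mean(np.diag(y)))}
        k = 1
    else:
        raise ValueError(f"unknown tuning model {model!r}")
    pred = tuning_predictions(model, spec, layout, params)
    err = sr_models.rmse(pred, y)
    b = sr_models.bic(n * err ** 2, n, k) if err > 0 else -np.inf
    return TuningFitResult(model=model, params=params, rmse=err, bic=b,
                           k_params=k)


def compare_tuning(coact_matrices: list[np.ndarray],
                   specs: list[SequenceSpec],
                   layout: StimulusLayout | None = None,
                   models: tuple[str, ...] = TUNING_MODELS) -> dict:
    """Per-subject fits of all tuning models and the group-level comparison."""
    if len(coact_matrices) < 2:
        raise ValueError("need at least two subjects")
    if layout is None:
        layout = geometry.build_layout()
    rows = []
    for s, (coact, spec) in enumerate(zip(coact_matrices, specs)):
        for m in models:
            fit = fit_tuning(coact, m, spec, layout)
            rows.append({"subject": s, "model": m, "rmse": fit.rmse,
                         "bic": fit.bic, **{f"param_{k}": v
                                            for k, v in fit.params.items()}})
    fits = pd.DataFrame(rows)
    mean_bic = fits.groupby("model")["bic"].mean()
    winner = mean_bic.idxmin()
    tests = {}
    for i, m1 in enumerate(models):
        for m2 in models[i + 1:]:
            x = fits.loc[fits.model == m1, "rmse"].to_numpy()
            y = fits.loc[fits.model == m2, "rmse"].to_numpy()
            if np.allclose(x, y):
                tests[f"{m1}_vs_{m2}"] = group_stats.GroupStatResult(
                    0.0, len(x) - 1, 1.0, "paired t", len(x))
            else:
                tests[f"{m1}_vs_{m2}"] = group_stats.paired_t(x, y)
    return {"fits": fits, "mean_bic": mean_bic.to_dict(), "winner": winner,
            "rmse_tests": tests}
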