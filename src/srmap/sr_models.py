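"""Successor-representation, co-occurrence and null models for partial-trial data.

The learned sequence A-B-C-D is a four-state chain with transition matrix T
(rows one-hot onto the next state, terminal row D all zero).  The successor
representation is the discounted predictive map

    M = (I - gamma T)^{-1} = I + gamma T + gamma^2 T^2 + ...

so for the chain M[i, j] = gamma^(j-i) for j >= i and 0 otherwise.  Presenting
a single sequence item s on a partial trial predicts activity a * M[s] across
the four sequence locations (SR), a constant off-diagonal reactivation omega
(CO), or stimulation only (H0).  A per-subject multiplicative scale a puts the
unit predictions on the scale of BOLD betas, so SR and CO carry two free
parameters and H0 one.

Model fits minimise the root-mean-square error over all 16 cells of the
4 x 4 activity profile (partial-trial type x sequence location); models are
compared by RMSE and by the Gaussian-error BIC, n ln(RSS/n) + k ln(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import stats as group_stats

MODELS = ("SR", "CO", "H0")
N_STATES = 4


def build_transition_matrix(cyclic: bool = False) -> np.ndarray:
    """Chain transition matrix for A-B-C-D; optionally close the loop D->A."""
    T = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES - 1):
        T[i, i + 1] = 1.0
    if cyclic:
        T[N_STATES - 1, 0] = 1.0
    return T


def successor_matrix(T: np.ndarray, gamma: float) -> np.ndarray:
    """M = (I - gamma T)^{-1}."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    eye = np.eye(T.shape[0])
    return np.linalg.inv(eye - gamma * T)


@dataclass
class ModelPrediction:
    model_id: str
    predicted: np.ndarray          # 4x4, partial-trial type x sequence location
    gamma: float | None = None
    omega: float | None = None
    scale: float = 1.0


def _unit_prediction(model_id: str, gamma: float | None = None,
                     omega: float | None = None,
                     cyclic: bool = False) -> np.ndarray:
    """Prediction matrix at scale 1 (row s = response profile after item s)."""
    if model_id == "SR":
        return successor_matrix(build_transition_matrix(cyclic), gamma)
    if model_id == "CO":
        P = np.full((N_STATES, N_STATES), omega, dtype=float)
        np.fill_diagonal(P, 1.0)
        return P
    if model_id == "H0":
        return np.eye(N_STATES)
    raise ValueError(f"unknown model {model_id!r}")


def predict_partial(model_id: str, params: dict,
                    cyclic: bool = False) -> ModelPrediction:
    """Scaled 4x4 model prediction for the four partial-trial types."""
    scale = float(params.get("scale", 1.0))
    unit = _unit_prediction(model_id, params.get("gamma"),
                            params.get("omega"), cyclic)
    return ModelPrediction(model_id=model_id, predicted=scale * unit,
                           gamma=params.get("gamma"),
                           omega=params.get("omega"), scale=scale)


def rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {observed.shape}")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def bic(rss: float, n: int, k: int) -> float:
    """Gaussian-error BIC up to an additive constant: n ln(RSS/n) + k ln(n)."""
    if n <= k or k < 0:
        raise ValueError(f"need n > k >= 0, got n={n}, k={k}")
    if rss <= 0:
        warnings.warn("zero residual sum of squares; BIC is -inf", RuntimeWarning)
        return -np.inf
    return float(n * np.log(rss / n) + k * np.log(n))


@dataclass
class ModelFitResult:
    model_id: str
    params: dict
    rmse: float
    bic: float
    n_points: int = 16
    k_params: int = field(default=2)


def _best_scale(unit: np.ndarray, observed: np.ndarray) -> float:
    """Least-squares multiplicative scale, clamped non-negative."""
    denom = float(np.sum(unit * unit))
    if denom == 0:
        return 0.0
    return max(0.0, float(np.sum(unit * observed)) / denom)


def _sr_rss(gamma: float, observed: np.ndarray, cyclic: bool) -> float:
    unit = _unit_prediction("SR", gamma=gamma, cyclic=cyclic)
    a = _best_scale(unit, observed)
    return float(np.sum((a * unit - observed) ** 2))


def fit_model(profile: np.ndarray, model_id: str,
              cyclic: bool = False) -> ModelFitResult:
    """Fit one model to a subject's 4x4 activity profile by least squares.

    SR: deterministic 0.01 grid on gamma in [0, 1] with the scale solved in
    closed form at each grid point, then bounded local refinement around the
    grid optimum.  CO: the prediction is linear in (a, a*omega), solved exactly
    by ordinary least squares.  H0: closed-form diagonal scale.
    """
    observed = np.asarray(profile, float)
    if observed.shape != (N_STATES, N_STATES) or not np.all(np.isfinite(observed)):
        raise ValueError("profile must be a complete, finite 4x4 matrix")
    n = observed.size

    if model_id == "SR":
        grid = np.arange(0.0, 1.0 + 1e-12, 0.01)
        losses = [_sr_rss(g, observed, cyclic) for g in grid]
        g0 = grid[int(np.argmin(losses))]
        lo, hi = max(0.0, g0 - 0.01), min(1.0, g0 + 0.01)
        res = minimize_scalar(_sr_rss, bounds=(lo, hi), args=(observed, cyclic),
                              method="bounded", options={"xatol": 1e-7})
        g_hat = float(res.x) if res.fun <= min(losses) else float(g0)
        unit = _unit_prediction("SR", gamma=g_hat, cyclic=cyclic)
        a = _best_scale(unit, observed)
        params = {"gamma": g_hat, "scale": a}
        k = 2
    elif model_id == "CO":
        diag = np.eye(N_STATES).ravel()
        off = (1.0 - np.eye(N_STATES)).ravel()
        X = np.column_stack([diag, off])
        coef, *_ = np.linalg.lstsq(X, observed.ravel(), rcond=None)
        a, b = float(coef[0]), float(coef[1])
        if a < 0:
            a, b = 0.0, 0.0
        omega = b / a if a > 0 else 0.0
        unit = _unit_prediction("CO", omega=omega)
        params = {"omega": omega, "scale": a}
        k = 2
    elif model_id == "H0":
        a = max(0.0, float(np.mean(np.diag(observed))))
        unit = np.eye(N_STATES)
        params = {"scale": a}
        k = 1
    else:
        raise ValueError(f"unknown model {model_id!r}")

    pred = params["scale"] * unit
    err = rmse(pred, observed)
    return ModelFitResult(model_id=model_id, params=params, rmse=err,
                          bic=bic(n * err ** 2, n, k) if err > 0 else -np.inf,
                          n_points=n, k_params=k)


def fit_gamma_decay(lag_profile: np.ndarray,
                    grid_step: float = 1e-3) -> tuple[float, float]:
    """Least-squares fit of a * gamma^lag to mean activity at lags 1, 2, ...

    gamma is constrained to [0, 1]; the amplitude is solved in closed form at
    each gamma.  Raises on an all-zero profile (gamma undefined).
    """
    y = np.asarray(lag_profile, float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("need at least two lag values")
    if np.allclose(y, 0.0):
        raise ValueError("all-zero lag profile: decay rate undefined")
    lags = np.arange(1, y.size + 1)

    def loss(g: float) -> float:
        basis = g ** lags
        denom = float(basis @ basis)
        a = float(basis @ y) / denom if denom > 0 else 0.0
        return float(np.sum((a * basis - y) ** 2))

    grid = np.arange(0.0, 1.0 + 1e-12, grid_step)
    g0 = grid[int(np.argmin([loss(g) for g in grid]))]
    res = minimize_scalar(loss, bounds=(max(0.0, g0 - grid_step),
                                        min(1.0, g0 + grid_step)),
                          method="bounded", options={"xatol": 1e-8})
    g_hat = float(res.x) if res.fun <= loss(g0) else float(g0)
    basis = g_hat ** lags
    a_hat = float(basis @ y) / float(basis @ basis) if np.any(basis) else 0.0
    return g_hat, a_hat


def model_comparison(cohort_profiles: list[np.ndarray],
                     models: tuple[str, ...] = MODELS) -> dict:
    """Per-subject fits of all models plus group-level comparison.

    Returns a dict with a tidy per-subject ``fits`` table, the group-mean BIC
    ``winner``, and paired t tests on RMSEs between every model pair.
    """
    if len(cohort_profiles) < 2:
        raise ValueError("need at least two subjects")
    rows = []
    for s, profile in enumerate(cohort_profiles):
        for m in models:
            fit = fit_model(profile, m)
            rows.append({"subject": s, "model": m,
                         "gamma": fit.params.get("gamma"),
                         "omega": fit.params.get("omega"),
                         "scale": fit.params.get("scale"),
                         "rmse": fit.rmse, "bic": fit.bic})
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
                    statistic=0.0, df=len(x) - 1, p_value=1.0,
                    test_name="paired t", n=len(x))
            else:
                tests[f"{m1}_vs_{m2}"] = group_stats.paired_t(x, y)
    return {"fits": fits, "mean_bic": mean_bic.to_dict(), "winner": winner,
            "rmse_tests": tests}
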