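"""Time-series forecasting backends for unconstrained coordinate series.

Four model families are supported, all consuming a plain real-valued series
(or a matrix of them for the vector-autoregressive family) and producing
k-step-ahead point forecasts:

* ``ARIMA`` — autoregressive integrated moving average, order chosen
  automatically by corrected AIC over a small (p, d, q) grid, with a drift
  term where the differencing order permits one.
* ``ETS`` — exponential smoothing in state-space form, error/trend
  configuration chosen by corrected AIC (no seasonality: the data are
  annual).
* ``VAR`` — vector autoregression on all coordinates jointly, lag order by
  information criterion.
* ``NNETTS`` — a single-hidden-layer nonlinear autoregression

      x_t = beta_0 + sum_j beta_j * g(gamma_0j + sum_i gamma_ij x_{t-i}),

  with logistic activation g, m lagged inputs and D_h hidden units, trained
  by least squares with seeded multi-start quasi-Newton optimisation.
  Multi-step forecasts iterate the fitted one-step map on its own output.

Every backend is a deterministic function of (series, config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

Family = Literal["ARIMA", "ETS", "VAR", "NNETTS"]

#: Families in the fixed comparison/tie-break order.
FAMILIES: tuple[str, ...] = ("ARIMA", "ETS", "VAR", "NNETTS")

DEFAULT_SEED = 20190411


class FitError(RuntimeError):
    """A backend could not be fitted to the given series."""


@dataclass(frozen=True)
class ModelConfig:
    """Configuration for one forecasting family.

    Family-specific fields are ignored by the other families.  ``seed``
    feeds every stochastic routine (only NNETTS training is stochastic).
    """

    family: str = "ARIMA"
    # ARIMA: automatic order search by AICc unless a fixed order is given
    arima_order: tuple[int, int, int] | None = None
    arima_max_p: int = 3
    arima_max_d: int = 2
    arima_max_q: int = 3
    # ETS: automatic error/trend selection unless a fixed trend is given
    ets_trend: str | None = "auto"  # None | "add" | "auto"
    # VAR
    var_max_lag: int = 5
    # NNETTS
    nnetts_lags: int = 2
    nnetts_hidden: int = 2
    restarts: int = 20
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.nnetts_lags < 1 or self.nnetts_hidden < 1 or self.restarts < 1:
            raise ValueError("nnetts_lags, nnetts_hidden and restarts must be >= 1")
        if self.var_max_lag < 1:
            raise ValueError("var_max_lag must be >= 1")


@dataclass
class FittedModel:
    """A fitted backend with in-sample fit and provenance.

    ``fitted_values`` are one-step in-sample predictions aligned with the
    tail of the training series starting at ``fitted_start`` (models with
    lags cannot predict the first few observations); ``residuals`` are
    observed minus fitted on that same range.
    """

    config: ModelConfig
    parameters: dict
    fitted_values: np.ndarray
    residuals: np.ndarray
    fitted_start: int
    training_log: dict = field(default_factory=dict)


def _check_series(y: np.ndarray, min_len: int, what: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError(f"{what}: expected a 1-D series")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"{what}: series contains non-finite values")
    if y.size < min_len:
        raise FitError(f"{what}: series length {y.size} < required {min_len}")
    return y


# ---------------------------------------------------------------------------
# ARIMA
# ---------------------------------------------------------------------------

def _fit_arima(y: np.ndarray, config: ModelConfig, k: int):
    from statsmodels.tsa.arima.model import ARIMA

    # zero-variance series: the likelihood is degenerate, the answer exact
    if np.ptp(y) < 1e-12:
        c = float(y[0])
        model = FittedModel(
            config=config,
            parameters={"constant": c},
            fitted_values=np.full_like(y, c),
            residuals=np.zeros_like(y),
            fitted_start=0,
            training_log={"note": "constant series shortcut"},
        )
        return model, np.full(k, c)
    if config.arima_order is not None:
        orders = [config.arima_order]
    else:
        orders = [
            (p, d, q)
            for d in range(config.arima_max_d + 1)
            for p in range(config.arima_max_p + 1)
            for q in range(config.arima_max_q + 1)
        ]
    best = None
    best_aicc = np.inf
    for p, d, q in orders:
        # deterministic-trend term compatible with the differencing order:
        # a mean for d=0, a drift for d=1, none for d=2
        trend = {0: "c", 1: "t", 2: "n"}[min(d, 2)]
        if p == d == q == 0 and trend == "n":
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ARIMA(y, order=(p, d, q), trend=trend).fit()
            aicc = res.aicc
        except Exception:
            continue
        if np.isfinite(aicc) and aicc < best_aicc:
            best_aicc = aicc
            best = (res, (p, d, q), trend)
    if best is None:
        raise FitError("no ARIMA candidate converged")
    res, order, trend = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fc = np.asarray(res.forecast(steps=k)) if k > 0 else np.empty(0)
        fitted = np.asarray(res.predict())
    model = FittedModel(
        config=replace(config, arima_order=order),
        parameters={"order": order, "trend": trend, "params": dict(res.params.items())
                    if hasattr(res.params, "items") else {"params": list(res.params)}},
        fitted_values=fitted,
        residuals=y - fitted,
        fitted_start=0,
        training_log={"aicc": float(best_aicc)},
    )
    return model, fc


# ---------------------------------------------------------------------------
# ETS
# ---------------------------------------------------------------------------

def _fit_ets(y: np.ndarray, config: ModelConfig, k: int):
    from statsmodels.tsa.exponential_smoothing.ets import ETSModel

    if config.ets_trend == "auto":
        candidates = [(None, False), ("add", False), ("add", True)]
    else:
        candidates = [(config.ets_trend, False)]
    # ETS requires strictly finite variance; a constant series is fitted
    # trivially (every smoothing state equals the constant)
    if np.ptp(y) < 1e-12:
        c = float(y[0])
        model = FittedModel(
            config=config,
            parameters={"constant": c},
            fitted_values=np.full_like(y, c),
            residuals=np.zeros_like(y),
            fitted_start=0,
            training_log={"note": "constant series shortcut"},
        )
        return model, np.full(k, c)
    best = None
    best_aicc = np.inf
    for trend, damped in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ETSModel(
                    y, error="add", trend=trend, damped_trend=damped
                ).fit(disp=False)
            aicc = res.aicc
        except Exception:
            continue
        if np.isfinite(aicc) and aicc < best_aicc:
            best_aicc = aicc
            best = (res, trend, damped)
    if best is None:
        raise FitError("no ETS candidate converged")
    res, trend, damped = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fc = np.asarray(res.forecast(steps=k)) if k > 0 else np.empty(0)
        fitted = np.asarray(res.fittedvalues)
    model = FittedModel(
        config=config,
        parameters={"trend": trend, "damped": damped,
                    "params": list(map(float, res.params))},
        fitted_values=fitted,
        residuals=y - fitted,
        fitted_start=0,
        training_log={"aicc": float(best_aicc)},
    )
    return model, fc


# ---------------------------------------------------------------------------
# NNETTS
# ---------------------------------------------------------------------------

def _nnetts_design(z: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Lag matrix X[t] = (z_{t-1}, ..., z_{t-m}) and target y[t] = z_t."""
    n = z.size
    X = np.column_stack([z[m - i - 1 : n - i - 1] for i in range(m)])
    return X, z[m:]


def _unpack(params: np.ndarray, m: int, h: int):
    beta0 = params[0]
    beta = params[1 : 1 + h]
    gamma0 = params[1 + h : 1 + 2 * h]
    gamma = params[1 + 2 * h :].reshape(h, m)
    return beta0, beta, gamma0, gamma


def _nnetts_loss_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray, m: int, h: int):
    beta0, beta, gamma0, gamma = _unpack(params, m, h)
    A = X @ gamma.T + gamma0          # (N, h)
    H = expit(A)
    pred = H @ beta + beta0
    r = pred - y
    n = y.size
    loss = float(r @ r) / n
    dpred = 2.0 * r / n
    g_beta0 = dpred.sum()
    g_beta = H.T @ dpred
    dA = (dpred[:, None] * beta[None, :]) * H * (1.0 - H)
    g_gamma0 = dA.sum(axis=0)
    g_gamma = dA.T @ X
    grad = np.concatenate([[g_beta0], g_beta, g_gamma0, g_gamma.ravel()])
    return loss, grad


def train_nnetts(
    series: np.ndarray,
    m: int,
    hidden: int,
    restarts: int = 20,
    seed: int = DEFAULT_SEED,
) -> FittedModel:
    """Fit the single-hidden-layer autoregression by multi-start least squares.

    The series is standardised internally (predictions are de-standardised
    on output).  ``restarts`` random initialisations (weights uniform on
    [-0.5, 0.5], seeded) are optimised with L-BFGS and the lowest final
    in-sample loss wins, so the final loss is monotonically non-increasing
    in the number of restarts for a fixed seed.
    """
    y = _check_series(series, m + 5, "NNETTS")
    if m < 1 or hidden < 1:
        raise ValueError("m and hidden must be >= 1")
    n_params = 1 + 2 * hidden + hidden * m
    if y.size <= m + hidden:
        raise FitError(
            f"NNETTS: series length {y.size} too short for m={m}, hidden={hidden}"
        )
    mu, sd = float(y.mean()), float(y.std())
    if sd < 1e-12:
        sd = 1.0
    z = (y - mu) / sd
    X, target = _nnetts_design(z, m)
    rng = np.random.default_rng(seed)
    best_params = None
    best_loss = np.inf
    losses = []
    for _ in range(restarts):
        x0 = rng.uniform(-0.5, 0.5, size=n_params)
        res = minimize(
            _nnetts_loss_grad,
            x0,
            args=(X, target, m, hidden),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 300},
        )
        losses.append(float(res.fun))
        if res.fun < best_loss:
            best_loss = float(res.fun)
            best_params = res.x
    beta0, beta, gamma0, gamma = _unpack(best_params, m, hidden)
    fitted_z = expit(X @ gamma.T + gamma0) @ beta + beta0
    fitted = fitted_z * sd + mu
    config = ModelConfig(
        family="NNETTS", nnetts_lags=m, nnetts_hidden=hidden,
        restarts=restarts, seed=seed,
    )
    return FittedModel(
        config=config,
        parameters={
            "beta0": float(beta0),
            "beta": beta.copy(),
            "gamma0": gamma0.copy(),
            "gamma": gamma.copy(),
            "activation": "logistic",
            "standardise": (mu, sd),
        },
        fitted_values=fitted,
        residuals=y[m:] - fitted,
        fitted_start=m,
        training_log={
            "seed": seed,
            "restarts": restarts,
            "final_loss": best_loss,
            "restart_losses": losses,
        },
    )


def _forecast_nnetts(model: FittedModel, series: np.ndarray, k: int) -> np.ndarray:
    """Recursive multi-step forecast: iterate the one-step map on its output."""
    p = model.parameters
    mu, sd = p["standardise"]
    m = p["gamma"].shape[1]
    hist = list((np.asarray(series, float) - mu) / sd)
    out = []
    for _ in range(k):
        x = np.array(hist[-1 : -m - 1 : -1])  # most recent first
        nxt = float(expit(p["gamma"] @ x + p["gamma0"]) @ p["beta"] + p["beta0"])
        hist.append(nxt)
        out.append(nxt)
    return np.array(out) * sd + mu


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def fit_forecast_univariate(
    series: np.ndarray, config: ModelConfig, k: int
) -> tuple[FittedModel, np.ndarray]:
    """Fit a univariate family (ARIMA, ETS or NNETTS) and forecast k steps."""
    if k < 0:
        raise ValueError("horizon k must be >= 0")
    if config.family == "ARIMA":
        y = _check_series(series, 10, "ARIMA")
        return _fit_arima(y, config, k)
    if config.family == "ETS":
        y = _check_series(series, 10, "ETS")
        return _fit_ets(y, config, k)
    if config.family == "NNETTS":
        y = _check_series(series, config.nnetts_lags + 5, "NNETTS")
        model = train_nnetts(
            y, config.nnetts_lags, config.nnetts_hidden, config.restarts, config.seed
        )
        return model, _forecast_nnetts(model, y, k)
    raise ValueError(f"{config.family} is not a univariate family")


def fit_forecast_var(
    series_matrix: np.ndarray, config: ModelConfig, k: int
) -> tuple[FittedModel, np.ndarray]:
    """Fit a VAR jointly on all columns and forecast k steps ahead.

    Lag order is chosen by AIC up to ``config.var_max_lag``.  A constant
    column makes the regression singular: if *all* columns are constant the
    forecast is that constant vector (nothing to estimate); if only some
    are, the fit fails naming the offending column.
    """
    from statsmodels.tsa.api import VAR

    Y = np.asarray(series_matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("VAR needs a (T, n_vars >= 2) matrix")
    if not np.all(np.isfinite(Y)):
        raise ValueError("VAR: series contains non-finite values")
    n_obs, n_vars = Y.shape
    if n_obs < config.var_max_lag * n_vars + 5:
        raise FitError(
            f"VAR: length {n_obs} < required {config.var_max_lag * n_vars + 5}"
        )
    const_cols = np.ptp(Y, axis=0) < 1e-12
    if const_cols.all():
        fitted = Y.copy()
        model = FittedModel(
            config=config,
            parameters={"note": "all columns constant"},
            fitted_values=fitted,
            residuals=Y - fitted,
            fitted_start=0,
            training_log={"lag_order": 0},
        )
        return model, np.tile(Y[-1], (max(k, 0), 1))
    if const_cols.any():
        raise FitError(
            f"VAR: column {int(np.argmax(const_cols))} is constant (singular design)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        var = VAR(Y)
        sel = var.select_order(maxlags=config.var_max_lag)
        lag = int(sel.aic) if sel.aic is not None else 1
        lag = max(lag, 1)
        res = var.fit(lag)
        fc = res.forecast(Y[-lag:], steps=k) if k > 0 else np.empty((0, n_vars))
        fitted = np.asarray(res.fittedvalues)
    model = FittedModel(
        config=config,
        parameters={"lag_order": lag, "coefs": res.coefs.copy(),
                    "intercept": np.asarray(res.params)[0].copy()},
        fitted_values=fitted,
        residuals=Y[lag:] - fitted,
        fitted_start=lag,
        training_log={"lag_order": lag, "aic": float(res.aic)},
    )
    return model, np.asarray(fc)
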