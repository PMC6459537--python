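"""End-to-end forecasting pipeline for compositional age structures.

The procedure has three steps, run for every candidate pairing of a
constraint-removal transform and a forecasting family:

1. transform the training compositions to unconstrained coordinates
   (ILR coordinates, hyperspherical angles, the retained parts of an LCC
   split, or the raw parts for the untransformed "Base" runs);
2. forecast each coordinate with the chosen family (univariate families
   coordinate-by-coordinate, the vector autoregression jointly);
3. back-transform the coordinate forecasts to compositions.

Candidates are scored on a held-out test window with CoDa-RMSE and
CoDa-MAPE, the winner is the lexicographic minimum (RMSE first, MAPE as
tie-break, then a fixed transform/model order), residuals are checked for
remaining serial structure with Box-Pierce and Ljung-Box portmanteau
tests, and the winning pairing is refit on the full series to produce the
future age-structure forecast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from . import backends, simplex
from .backends import FAMILIES, FitError, FittedModel, ModelConfig
from .simplex import (
    Composition,
    CompositionSeries,
    IlrCoordinates,
    clamp_angles,
    closure,
    coda_errors,
    drht_forward,
    drht_inverse,
    ilr_forward,
    ilr_inverse,
    lcc_complete,
    repair_lcc,
)

#: Transforms in the fixed tie-break order.
TRANSFORM_ORDER: tuple[str, ...] = ("ILR", "DRHT", "LCC.Y", "LCC.M", "LCC.O", "Base")

#: Component dropped (modelled as the complement) by each LCC variant.
LCC_DROPPED = {"LCC.Y": 0, "LCC.M": 1, "LCC.O": 2}

#: NNETTS tuning sub-grid: lag count x hidden-unit count.
NNETTS_LAG_GRID: tuple[int, ...] = (1, 2, 3)
NNETTS_HIDDEN_GRID: tuple[int, ...] = (1, 2, 3, 4, 5)


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesSplit:
    train: CompositionSeries
    test: CompositionSeries

    def __post_init__(self) -> None:
        if len(self.train) < 1 or len(self.test) < 1:
            raise PipelineError("both partitions must be non-empty")
        if self.train.years[-1] >= self.test.years[0]:
            raise PipelineError("train years must strictly precede test years")


def split_series(series: CompositionSeries, train_end_year: int) -> SeriesSplit:
    """Split at a calendar year: train = years <= boundary, test = the rest."""
    tr = [i for i, y in enumerate(series.years) if y <= train_end_year]
    te = [i for i, y in enumerate(series.years) if y > train_end_year]
    if not tr or not te:
        raise PipelineError(
            f"train_end_year={train_end_year} leaves an empty partition "
            f"(observed range {series.years[0]}..{series.years[-1]})"
        )
    pick = lambda idx: CompositionSeries(
        tuple(series.years[i] for i in idx), tuple(series.values[i] for i in idx)
    )
    return SeriesSplit(pick(tr), pick(te))


# ---------------------------------------------------------------------------
# Transform layer: compositions <-> coordinate matrices
# ---------------------------------------------------------------------------

def _to_coordinates(
    train: CompositionSeries, transform: str, epsilon: float | None
) -> np.ndarray:
    """(T, c) matrix of unconstrained coordinates for the given transform."""
    if transform == "ILR":
        return np.vstack([ilr_forward(x, epsilon).w for x in train.values])
    if transform == "DRHT":
        return np.vstack([drht_forward(x).theta for x in train.values])
    if transform in LCC_DROPPED:
        drop = LCC_DROPPED[transform]
        M = train.as_matrix()
        return np.delete(M, drop, axis=1)
    if transform == "Base":
        return train.as_matrix()
    raise ValueError(
        f"unknown transform {transform!r}; choose from {TRANSFORM_ORDER}"
    )


def _from_coordinates(
    F: np.ndarray,
    transform: str,
    labels: tuple[str, ...] | None,
    epsilon: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Back-transform forecast coordinates to (parts matrix, validity flags)."""
    rows, valid = [], []
    for row in np.atleast_2d(F):
        if transform == "ILR":
            rows.append(ilr_inverse(IlrCoordinates(row), labels).parts)
            valid.append(True)
        elif transform == "DRHT":
            rows.append(drht_inverse(clamp_angles(row), labels).parts)
            valid.append(True)
        elif transform in LCC_DROPPED:
            res = lcc_complete(row, LCC_DROPPED[transform])
            rows.append(res.parts)
            valid.append(res.valid)
        elif transform == "Base":
            # raw-scale forecasts need not respect the simplex: re-close,
            # clipping any negative part first
            rows.append(
                closure(np.clip(row, epsilon, None), labels).parts
            )
            valid.append(bool(np.all(row >= 0)))
        else:
            raise ValueError(f"unknown transform {transform!r}")
    return np.vstack(rows), np.array(valid, dtype=bool)


# ---------------------------------------------------------------------------
# Forecast result container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForecastResult:
    """Future-year compositions with provenance.

    ``parts`` holds the raw back-transformed values; for the LCC paths
    these can leave [0, 1] and the corresponding ``valid`` flag is False.
    """

    years: tuple[int, ...]
    parts: np.ndarray
    valid: tuple[bool, ...]
    transform: str
    family: str
    config: ModelConfig
    labels: tuple[str, ...] | None = None
    fitted: tuple[FittedModel, ...] = ()

    @property
    def horizon(self) -> int:
        return len(self.years)

    def compositions(self, epsilon: float = simplex.DEFAULT_EPSILON) -> CompositionSeries:
        """Forecasts as a valid CompositionSeries (invalid LCC rows repaired)."""
        rows = []
        for yr, row, ok in zip(self.years, self.parts, self.valid):
            if ok:
                rows.append(closure(np.clip(row, 0.0, None), self.labels).parts)
            else:
                rows.append(
                    repair_lcc(row, epsilon, self.labels, context=f"year {yr}").parts
                )
        return CompositionSeries.from_matrix(self.years, np.vstack(rows), self.labels)


def forecast_composition(
    train: CompositionSeries,
    transform: str,
    config: ModelConfig,
    k: int,
    epsilon: float = simplex.DEFAULT_EPSILON,
) -> ForecastResult:
    """Transform, forecast each coordinate, and back-transform k steps ahead."""
    if k < 1:
        raise ValueError("horizon k must be >= 1")
    C = _to_coordinates(train, transform, epsilon)
    fitted: list[FittedModel] = []
    try:
        if config.family == "VAR":
            if transform == "Base":
                # raw shares sum to 1 exactly, so a VAR on all D columns is
                # singular; fit jointly on the first D-1 parts and complete
                # the last by its complement before re-closing
                model, Fr = backends.fit_forecast_var(C[:, :-1], config, k)
                F = np.column_stack([Fr, 1.0 - Fr.sum(axis=1)])
            else:
                model, F = backends.fit_forecast_var(C, config, k)
            fitted.append(model)
        else:
            cols = []
            for j in range(C.shape[1]):
                model, fc = backends.fit_forecast_univariate(C[:, j], config, k)
                fitted.append(model)
                cols.append(fc)
            F = np.column_stack(cols)
    except (FitError, ValueError) as exc:
        raise FitError(f"[{transform}, coordinate fit] {exc}") from exc
    parts, valid = _from_coordinates(F, transform, train.labels, epsilon)
    years = tuple(range(train.years[-1] + 1, train.years[-1] + 1 + k))
    return ForecastResult(
        years=years,
        parts=parts,
        valid=tuple(bool(v) for v in valid),
        transform=transform,
        family=config.family,
        config=config,
        labels=train.labels,
        fitted=tuple(fitted),
    )


# ---------------------------------------------------------------------------
# Grid evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellResult:
    coda_rmse: float | None
    coda_mape: float | None
    config: ModelConfig | None = None
    warnings: tuple[str, ...] = ()
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None and self.coda_rmse is not None


@dataclass
class EvaluationReport:
    """CoDa-RMSE / CoDa-MAPE for every (transform, model) pairing."""

    entries: dict[tuple[str, str], CellResult]
    train_years: tuple[int, int]
    test_years: tuple[int, int]
    seed: int = backends.DEFAULT_SEED
    nnetts_grid: dict[tuple[str, int, int], CellResult] = field(default_factory=dict)

    def successful(self) -> dict[tuple[str, str], CellResult]:
        return {k: v for k, v in self.entries.items() if v.ok}


def _score(
    forecast: ForecastResult,
    test: CompositionSeries,
    epsilon: float,
) -> tuple[float, float, tuple[str, ...]]:
    warns = tuple(
        f"invalid composition forecast for year {yr}"
        for yr, ok in zip(forecast.years, forecast.valid)
        if not ok
    )
    rmse, mape = coda_errors(test, forecast.compositions(epsilon), epsilon)
    return rmse, mape, warns


ForecastFn = Callable[[CompositionSeries, str, ModelConfig, int], ForecastResult]


def tune_nnetts(
    split: SeriesSplit,
    transform: str,
    base_config: ModelConfig,
    epsilon: float = simplex.DEFAULT_EPSILON,
    lag_grid: Sequence[int] = NNETTS_LAG_GRID,
    hidden_grid: Sequence[int] = NNETTS_HIDDEN_GRID,
    forecast_fn: ForecastFn | None = None,
) -> tuple[ModelConfig, dict[tuple[str, int, int], CellResult]]:
    """Choose (lags, hidden units) for the neural autoregression.

    Every cell of the lag x hidden sub-grid is scored on the same
    out-of-sample window as the main comparison; the lowest CoDa-RMSE wins
    (MAPE, then smaller lags/hidden, as tie-breaks).
    """
    fn = forecast_fn or (
        lambda tr, t, c, k: forecast_composition(tr, t, c, k, epsilon)
    )
    k = len(split.test)
    cells: dict[tuple[str, int, int], CellResult] = {}
    best_key: tuple[float, float, int, int] | None = None
    best_cfg = None
    for m in lag_grid:
        for h in hidden_grid:
            cfg = replace(
                base_config, family="NNETTS", nnetts_lags=m, nnetts_hidden=h
            )
            try:
                fc = fn(split.train, transform, cfg, k)
                rmse, mape, warns = _score(fc, split.test, epsilon)
                cells[(transform, m, h)] = CellResult(rmse, mape, cfg, warns)
            except (FitError, ValueError) as exc:
                cells[(transform, m, h)] = CellResult(None, None, cfg, error=str(exc))
                continue
            key = (rmse, mape, m, h)
            if best_key is None or key < best_key:
                best_key, best_cfg = key, cfg
    if best_cfg is None:
        raise PipelineError(f"all NNETTS sub-grid cells failed for {transform}")
    return best_cfg, cells


def evaluate_grid(
    series: CompositionSeries,
    train_end_year: int,
    transforms: Sequence[str] = TRANSFORM_ORDER,
    families: Sequence[str] = FAMILIES,
    configs: Mapping[str, ModelConfig] | None = None,
    epsilon: float = simplex.DEFAULT_EPSILON,
    seed: int = backends.DEFAULT_SEED,
    forecast_fn: ForecastFn | None = None,
) -> EvaluationReport:
    """Score every transform x model pairing on the held-out window.

    ``configs`` optionally overrides the default per-family configuration.
    The NNETTS (lags, hidden) pairing is tuned per transform on its
    sub-grid before entering the main comparison.  Cell-level failures are
    recorded in the report rather than raised.
    """
    split = split_series(series, train_end_year)
    k = len(split.test)
    fn = forecast_fn or (
        lambda tr, t, c, kk: forecast_composition(tr, t, c, kk, epsilon)
    )
    configs = dict(configs or {})
    entries: dict[tuple[str, str], CellResult] = {}
    nnetts_grid: dict[tuple[str, int, int], CellResult] = {}
    for transform in transforms:
        for family in families:
            cfg = configs.get(family, ModelConfig(family=family, seed=seed))
            cfg = replace(cfg, family=family, seed=seed)
            try:
                if family == "NNETTS":
                    cfg, cells = tune_nnetts(
                        split, transform, cfg, epsilon, forecast_fn=forecast_fn
                    )
                    nnetts_grid.update(cells)
                fc = fn(split.train, transform, cfg, k)
                rmse, mape, warns = _score(fc, split.test, epsilon)
                entries[(transform, family)] = CellResult(rmse, mape, cfg, warns)
            except (FitError, ValueError, PipelineError) as exc:
                entries[(transform, family)] = CellResult(
                    None, None, cfg, error=str(exc)
                )
    return EvaluationReport(
        entries=entries,
        train_years=(split.train.years[0], split.train.years[-1]),
        test_years=(split.test.years[0], split.test.years[-1]),
        seed=seed,
        nnetts_grid=nnetts_grid,
    )


def select_best(
    report: EvaluationReport,
    exclude_transforms: Sequence[str] = (),
    exclude_models: Sequence[str] = (),
) -> tuple[str, str, float, float]:
    """Pick the winning (transform, model) cell.

    Lexicographic argmin: CoDa-RMSE first, CoDa-MAPE as tie-break, then
    the fixed transform order (ILR < DRHT < LCC.Y < LCC.M < LCC.O < Base)
    and model order (ARIMA < ETS < VAR < NNETTS).  Exclusion filters allow
    restricting the candidate set (e.g. to the one-to-one compositional
    transforms).
    """
    candidates = {
        (t, f): c
        for (t, f), c in report.successful().items()
        if t not in exclude_transforms and f not in exclude_models
    }
    if not candidates:
        raise PipelineError("no successful cells to select from")
    t_rank = {t: i for i, t in enumerate(TRANSFORM_ORDER)}
    f_rank = {f: i for i, f in enumerate(FAMILIES)}
    key = lambda item: (
        item[1].coda_rmse,
        item[1].coda_mape,
        t_rank.get(item[0][0], len(t_rank)),
        f_rank.get(item[0][1], len(f_rank)),
    )
    (transform, family), cell = min(candidates.items(), key=key)
    return transform, family, cell.coda_rmse, cell.coda_mape


# ---------------------------------------------------------------------------
# Residual diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WhiteNoiseResult:
    bp_stat: float
    bp_p: float
    lb_stat: float
    lb_p: float
    lags: int
    n: int


def residual_white_noise(residuals: np.ndarray, lags: int) -> WhiteNoiseResult:
    """Box-Pierce and Ljung-Box portmanteau tests for white-noise residuals.

    With r_j the lag-j sample autocorrelation of the n residuals:

        Q_BP = n * sum_{j<=h} r_j^2
        Q_LB = n (n + 2) * sum_{j<=h} r_j^2 / (n - j)

    both referred to a chi-square distribution with h degrees of freedom.
    A p-value above the significance level (conventionally 0.05) is
    consistent with no remaining serial structure.
    """
    e = np.asarray(residuals, dtype=float)
    n = e.size
    if lags < 1:
        raise ValueError("lags must be >= 1")
    if n < lags + 1:
        raise ValueError(f"need at least lags+1={lags + 1} residuals, got {n}")
    c = e - e.mean()
    denom = float(c @ c)
    if denom < 1e-300 or np.ptp(e) < 1e-14:
        raise ValueError("constant residual series: autocorrelation undefined")
    j = np.arange(1, lags + 1)
    r = np.array([float(c[jj:] @ c[:-jj]) / denom for jj in j])
    bp = n * float(np.sum(r**2))
    lb = n * (n + 2.0) * float(np.sum(r**2 / (n - j)))
    return WhiteNoiseResult(
        bp_stat=bp,
        bp_p=float(stats.chi2.sf(bp, lags)),
        lb_stat=lb,
        lb_p=float(stats.chi2.sf(lb, lags)),
        lags=lags,
        n=n,
    )


def default_lags(n: int) -> int:
    """Default portmanteau lag count: min(10, floor(n/5))."""
    return max(1, min(10, n // 5))


@dataclass
class DiagnosticsReport:
    """Per-component white-noise tests of original-scale fit residuals."""

    transform: str
    family: str
    results: dict[str, WhiteNoiseResult]


def residual_diagnostics(
    train: CompositionSeries,
    transform: str,
    config: ModelConfig,
    lags: int | None = None,
    epsilon: float = simplex.DEFAULT_EPSILON,
) -> DiagnosticsReport:
    """Portmanteau tests of in-sample residuals on the proportion scale.

    The model is fitted on the training window; its in-sample one-step
    coordinate predictions are back-transformed to compositions, and the
    per-component residual series (observed minus fitted proportion) are
    tested for remaining autocorrelation.
    """
    fc = forecast_composition(train, transform, config, k=1, epsilon=epsilon)
    start = max(m.fitted_start for m in fc.fitted)
    if config.family == "VAR":
        fitted_coords = fc.fitted[0].fitted_values
        if transform == "Base" and fitted_coords.shape[1] == train.D - 1:
            fitted_coords = np.column_stack(
                [fitted_coords, 1.0 - fitted_coords.sum(axis=1)]
            )
    else:
        fitted_coords = np.column_stack(
            [m.fitted_values[start - m.fitted_start :] for m in fc.fitted]
        )
    parts, _ = _from_coordinates(fitted_coords, transform, train.labels, epsilon)
    fitted_parts = np.vstack(
        [closure(np.clip(row, epsilon, None)).parts for row in parts]
    )
    observed = train.as_matrix()[start:]
    resid = observed - fitted_parts
    n = resid.shape[0]
    h = lags if lags is not None else default_lags(n)
    labels = train.labels or tuple(f"part{i + 1}" for i in range(train.D))
    results = {
        lab: residual_white_noise(resid[:, j], h) for j, lab in enumerate(labels)
    }
    return DiagnosticsReport(transform=transform, family=config.family, results=results)


# ---------------------------------------------------------------------------
# Final forecast
# ---------------------------------------------------------------------------

def forecast_future(
    series: CompositionSeries,
    transform: str,
    config: ModelConfig,
    horizon: int = 18,
    epsilon: float = simplex.DEFAULT_EPSILON,
) -> ForecastResult:
    """Refit the winning pairing on the full series and forecast the future."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    return forecast_composition(series, transform, config, horizon, epsilon)
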