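"""Synthetic compositional age-structure series with known ground truth.

The generator produces annual three-part (young / middle-aged / old)
compositions whose ILR pivot coordinates follow a linear trend plus
stationary AR(1) noise:

    w_t = a + b * t + e_t,        e_t = phi * e_{t-1} + eps_t,
    eps_t ~ N(0, sigma^2 I),      e_0 = 0,
    x_t  = ilr_inverse(w_t).

A linear drift in log-ratio space yields the smooth, monotone-ish share
trajectories seen in national age-structure data (declining young share,
rising old share) while keeping every simulated composition strictly
positive and exactly unit-sum.  The AR(1) term adds the serial correlation
that annual demographic shares exhibit.  Because the trend is linear in ILR
space, the noiseless path has a closed form, which makes forecast accuracy
checkable against an analytic continuation.

Presets emulate the qualitative trend shapes of three national series:
``china-like`` (steep young decline, fast ageing), ``india-like`` (rising
middle share, slow ageing) and ``vietnam-like`` (moderate versions of the
same).  Preset numbers are library constants chosen for shape, not
estimates of any published series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .simplex import (
    AGE_LABELS,
    Composition,
    CompositionSeries,
    IlrCoordinates,
    ilr_forward,
    ilr_inverse,
)


@dataclass(frozen=True)
class ScenarioParams:
    """Parameters of the linear-ILR-trend + AR(1)-noise generator.

    Attributes
    ----------
    D : number of parts (D-1 ILR coordinates).
    a, b : ILR intercepts and per-year slopes (log-ratio units).
    phi : AR(1) coefficient of the noise, |phi| < 1.
    sigma : innovation standard deviation (log-ratio units).
    n : number of annual observations.
    start_year : calendar year of the first observation.
    seed : RNG seed; identical params give a bit-identical series.
    """

    D: int = 3
    a: tuple[float, ...] = (0.0, 0.0)
    b: tuple[float, ...] = (0.0, 0.0)
    phi: float = 0.5
    sigma: float = 0.05
    n: int = 57
    start_year: int = 1960
    seed: int = 0
    labels: tuple[str, ...] | None = AGE_LABELS

    def __post_init__(self) -> None:
        if self.D < 2:
            raise ValueError("D must be >= 2")
        if len(self.a) != self.D - 1 or len(self.b) != self.D - 1:
            raise ValueError("a and b must have length D-1")
        if not abs(self.phi) < 1:
            raise ValueError("phi must satisfy |phi| < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.labels is not None and len(self.labels) != self.D:
            object.__setattr__(self, "labels", None)


def mean_path(params: ScenarioParams) -> CompositionSeries:
    """The noiseless trajectory x_t = ilr_inverse(a + b*t), t = 0..n-1."""
    return simulate_coda_series(replace(params, sigma=0.0))


def simulate_coda_series(params: ScenarioParams) -> CompositionSeries:
    """Draw one series from the generator (deterministic in the seed)."""
    a = np.asarray(params.a, float)
    b = np.asarray(params.b, float)
    rng = np.random.default_rng(params.seed)
    rows = []
    e = np.zeros(params.D - 1)
    for t in range(params.n):
        if params.sigma > 0:
            e = params.phi * e + rng.normal(0.0, params.sigma, params.D - 1)
        w = a + b * t + e
        rows.append(ilr_inverse(IlrCoordinates(w), params.labels).parts)
    years = range(params.start_year, params.start_year + params.n)
    return CompositionSeries.from_matrix(years, np.vstack(rows), params.labels)


#: Qualitative national-trend presets (three parts, 57 annual observations).
_PRESETS: dict[str, ScenarioParams] = {
    # steep decline of the young share, middle rises then the old share
    # accelerates: fast demographic transition
    "china-like": ScenarioParams(
        a=(-0.225, 1.83), b=(-0.0138, -0.0156), phi=0.5, sigma=0.05, seed=0
    ),
    # young share declines slowly, middle share keeps rising, ageing slow
    "india-like": ScenarioParams(
        a=(-0.22, 2.26), b=(-0.0069, -0.0117), phi=0.5, sigma=0.04, seed=0
    ),
    # moderate decline of the young share and moderate ageing
    "vietnam-like": ScenarioParams(
        a=(-0.165, 1.83), b=(-0.0111, -0.0073), phi=0.5, sigma=0.045, seed=0
    ),
}


def scenario_presets(name: str) -> ScenarioParams:
    """Return the fixed parameter set for a named scenario."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {sorted(_PRESETS)}"
        ) from None


def recover_parameters(
    series: CompositionSeries,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Estimate (a, b, phi, sigma) back from a simulated series.

    Per ILR coordinate, ordinary least squares of w_t on t gives the
    intercept and slope; the detrended residuals, pooled across
    coordinates, give the AR(1) coefficient (least squares of e_t on
    e_{t-1}) and the innovation standard deviation.
    """
    n = len(series)
    if n < 10:
        raise ValueError(f"need at least 10 observations, got {n}")
    W = np.vstack([ilr_forward(x).w for x in series.values])
    if not np.all(np.isfinite(W)):
        raise ValueError("degenerate series: non-finite ILR coordinates")
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(X, W, rcond=None)
    a_hat, b_hat = coef[0], coef[1]
    E = W - X @ coef
    lagged = E[:-1].ravel()
    current = E[1:].ravel()
    denom = float(lagged @ lagged)
    phi_hat = float(current @ lagged / denom) if denom > 1e-20 else 0.0
    innov = current - phi_hat * lagged
    sigma_hat = float(np.sqrt(np.mean(innov**2)))
    return a_hat, b_hat, phi_hat, sigma_hat
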