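"""Core compositional-data types, simplex transforms and Aitchison metrics.

A *composition* is a vector of D nonnegative parts carrying only relative
information, constrained to the unit simplex (parts sum to 1).  Standard
time-series machinery misbehaves on the simplex, so forecasting proceeds by
mapping compositions to unconstrained coordinates, modelling those, and
mapping forecasts back.  Three constraint-removal maps are provided:

* **ILR** — isometric log-ratio pivot coordinates.  The D-simplex maps to
  R^(D-1) isometrically with respect to the Aitchison metric; requires
  strictly positive parts (zeros handled by multiplicative replacement).
* **DRHT** — dimension reduction through a hyperspherical transformation.
  Square-rooted parts lie on the unit (D-1)-sphere and are encoded as D-1
  polar angles in [0, pi/2]; tolerates zero parts.
* **LCC** — linear combined component.  D-1 parts are modelled directly and
  the remaining part is defined as one minus their sum; cheap, but the
  completed part can leave [0, 1], so results carry validity flags.

Forecast accuracy on the simplex is scored with the Aitchison distance
(Euclidean distance between centred-log-ratio images) and the derived
CoDa-RMSE / CoDa-MAPE aggregates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger("codaf")

#: Default replacement value for zero parts in log-ratio operations.
DEFAULT_EPSILON = 1e-6

#: Fixed component-order convention for three-part age structures.
AGE_LABELS = ("young", "middle", "old")


class ConstraintError(ValueError):
    """A vector violates the simplex (nonnegativity / unit-sum) constraints."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Composition:
    """A D-part composition on the unit simplex.

    Parameters
    ----------
    parts
        Length-D vector of proportions in [0, 1] summing to 1 (checked to
        1e-9).
    labels
        Optional component names, e.g. ``("young", "middle", "old")``.
    """

    parts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        parts = np.asarray(self.parts, dtype=float)
        object.__setattr__(self, "parts", parts)
        if parts.ndim != 1 or parts.size < 2:
            raise ConstraintError("a composition needs at least 2 parts")
        if np.any(parts < -1e-12):
            idx = int(np.argmin(parts))
            raise ConstraintError(f"negative part at index {idx}: {parts[idx]}")
        if abs(parts.sum() - 1.0) > 1e-9:
            raise ConstraintError(f"parts sum to {parts.sum()!r}, not 1")
        if self.labels is not None and len(self.labels) != parts.size:
            raise ConstraintError("labels length must match number of parts")

    @property
    def D(self) -> int:
        return self.parts.size

    def to_list(self) -> list[float]:
        return [float(p) for p in self.parts]


@dataclass(frozen=True)
class CompositionSeries:
    """A time-ordered sequence of compositions indexed by integer years."""

    years: tuple[int, ...]
    values: tuple[Composition, ...]

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        values = tuple(self.values)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if len(years) != len(values) or len(years) < 1:
            raise ValueError("years and values must align and be non-empty")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        D = values[0].D
        if any(v.D != D for v in values):
            raise ValueError("all compositions must share the same D")

    @property
    def D(self) -> int:
        return self.values[0].D

    @property
    def labels(self) -> tuple[str, ...] | None:
        return self.values[0].labels

    def __len__(self) -> int:
        return len(self.years)

    def as_matrix(self) -> np.ndarray:
        """(T, D) array of parts, rows in year order."""
        return np.vstack([v.parts for v in self.values])

    @staticmethod
    def from_matrix(
        years: Sequence[int],
        matrix: np.ndarray,
        labels: tuple[str, ...] | None = None,
    ) -> "CompositionSeries":
        values = tuple(Composition(row, labels) for row in np.asarray(matrix, float))
        return CompositionSeries(tuple(int(y) for y in years), values)


@dataclass(frozen=True)
class IlrCoordinates:
    """Unconstrained ILR pivot coordinates, length D-1."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if not np.all(np.isfinite(w)):
            raise ValueError("ILR coordinates must be finite")


@dataclass(frozen=True)
class ClrVector:
    """Centred log-ratio vector: length D, entries sum to zero."""

    v: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "v", v)
        if abs(v.sum()) > 1e-9:
            raise ValueError(f"clr entries must sum to 0, got {v.sum()!r}")


@dataclass(frozen=True)
class HypersphericalAngles:
    """Polar angles theta_2..theta_D of the square-root composition, radians."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if np.any(theta < -1e-12) or np.any(theta > math.pi / 2 + 1e-12):
            raise ValueError("angles must lie in [0, pi/2]")


# ---------------------------------------------------------------------------
# Closure and zero replacement
# ---------------------------------------------------------------------------

def closure(raw: Sequence[float], labels: tuple[str, ...] | None = None) -> Composition:
    """Renormalise a nonnegative vector to unit sum.

    Raises :class:`ConstraintError` for negative entries (naming the index)
    or an all-zero vector.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ConstraintError("need at least 2 parts")
    neg = np.where(arr < 0)[0]
    if neg.size:
        raise ConstraintError(f"negative entry at index {int(neg[0])}: {arr[neg[0]]}")
    total = arr.sum()
    if total <= 0:
        raise ConstraintError("all-zero input cannot be closed to the simplex")
    return Composition(arr / total, labels)


def replace_zeros(x: Composition, epsilon: float | None = DEFAULT_EPSILON) -> Composition:
    """Multiplicative zero replacement.

    Zero parts are set to ``epsilon`` and the non-zero parts are scaled down
    proportionally so the result still sums to 1.  With ``epsilon=None`` the
    policy is disabled and a zero part raises.
    """
    parts = x.parts
    zero = parts <= 0
    if not zero.any():
        return x
    if epsilon is None:
        idx = int(np.argmax(zero))
        raise ConstraintError(
            f"zero part at index {idx} with zero-replacement disabled"
        )
    n_zero = int(zero.sum())
    logger.warning("replacing %d zero part(s) with epsilon=%g", n_zero, epsilon)
    out = parts * (1.0 - n_zero * epsilon)
    out[zero] = epsilon
    return closure(out, x.labels)


# ---------------------------------------------------------------------------
# ILR pivot transform
# ---------------------------------------------------------------------------

def ilr_forward(x: Composition, epsilon: float | None = DEFAULT_EPSILON) -> IlrCoordinates:
    """Map a composition to ILR pivot coordinates.

    w_d = sqrt(d/(d+1)) * ln( gm(x_1..x_d) / x_{d+1} ),  d = 1..D-1,

    where gm is the geometric mean of the first d parts.  Zero parts are
    first handled by :func:`replace_zeros`.
    """
    x = replace_zeros(x, epsilon)
    lx = np.log(x.parts)
    D = x.D
    d = np.arange(1, D)
    # cumulative mean of logs = log of running geometric mean
    gm_log = np.cumsum(lx)[:-1] / d
    w = np.sqrt(d / (d + 1.0)) * (gm_log - lx[1:])
    return IlrCoordinates(w)


def clr_from_ilr(w: IlrCoordinates) -> ClrVector:
    """Expand ILR pivot coordinates to the centred log-ratio vector.

    v_d = sum_{i=d..D-1} w_i / sqrt(i(i+1)) - sqrt((d-1)/d) * w_{d-1},
    with w_0 = w_D = 0.  The result sums to zero by construction.
    """
    wv = w.w
    D = wv.size + 1
    i = np.arange(1, D)
    terms = wv / np.sqrt(i * (i + 1.0))
    # tail sums: sum_{i=d}^{D-1} terms[i-1] for d = 1..D (empty for d = D)
    tail = np.concatenate([np.cumsum(terms[::-1])[::-1], [0.0]])
    d = np.arange(1, D + 1)
    pivot = np.concatenate([[0.0], np.sqrt((d[1:] - 1.0) / d[1:]) * wv])
    return ClrVector(tail - pivot)


def ilr_inverse(
    w: IlrCoordinates, labels: tuple[str, ...] | None = None
) -> Composition:
    """Map ILR coordinates back to the simplex (softmax of the clr vector)."""
    if not np.all(np.isfinite(w.w)):
        raise ValueError("non-finite ILR coordinates")
    v = clr_from_ilr(w).v
    e = np.exp(v - v.max())  # shift for overflow safety; cancels in closure
    return closure(e, labels)


# ---------------------------------------------------------------------------
# Hyperspherical (DRHT) transform
# ---------------------------------------------------------------------------

def drht_forward(x: Composition) -> HypersphericalAngles:
    """Encode a composition as polar angles of its square-root vector.

    With y_d = sqrt(x_d) (so sum y^2 = 1):

        theta_D = arccos(y_D)
        theta_d = arccos( y_d / prod_{i=d+1..D} sin theta_i ),  d = D-1..2.

    When the accumulated sine product underflows (all remaining mass is
    zero) the remaining angles are set to 0; any value would reproduce the
    composition under the inverse map, so the convention only fixes the
    representation.  arccos arguments are clamped to [0, 1].
    """
    y = np.sqrt(x.parts)
    D = x.D
    theta = np.zeros(D - 1)  # theta[j] holds theta_{j+2}
    sin_prod = 1.0
    for d in range(D, 1, -1):
        if sin_prod < 1e-12:
            theta[: d - 1] = 0.0
            break
        c = min(1.0, max(0.0, y[d - 1] / sin_prod))
        t = math.acos(c)
        theta[d - 2] = t
        sin_prod *= math.sin(t)
    return HypersphericalAngles(theta)


def drht_inverse(
    theta: HypersphericalAngles, labels: tuple[str, ...] | None = None
) -> Composition:
    """Decode polar angles back to a composition.

        x_1 = (prod_{i=2..D} sin theta_i)^2
        x_d = (cos theta_d * prod_{i=d+1..D} sin theta_i)^2,  2 <= d <= D-1
        x_D = (cos theta_D)^2

    Forecasted angles that left [0, pi/2] must be clipped upstream via
    :func:`clamp_angles`.  The output sums to 1 exactly up to floating
    point, being a squared point on the unit sphere.
    """
    t = theta.theta
    D = t.size + 1
    x = np.empty(D)
    sin_prod = 1.0
    for d in range(D, 1, -1):
        ang = t[d - 2]
        x[d - 1] = (math.cos(ang) * sin_prod) ** 2
        sin_prod *= math.sin(ang)
    x[0] = sin_prod**2
    return Composition(x / x.sum(), labels)


def clamp_angles(raw: np.ndarray) -> HypersphericalAngles:
    """Clip forecasted angles into [0, pi/2], warning with the clip count."""
    arr = np.asarray(raw, dtype=float)
    clipped = np.clip(arr, 0.0, math.pi / 2)
    n_clamped = int(np.sum(clipped != arr))
    if n_clamped:
        logger.warning("clamped %d forecasted angle(s) into [0, pi/2]", n_clamped)
    return HypersphericalAngles(clipped)


# ---------------------------------------------------------------------------
# Linear combined component (LCC)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LccResult:
    """A completed (possibly invalid) composition vector from the LCC path."""

    parts: np.ndarray
    valid: bool
    dropped_index: int


def lcc_complete(retained: Sequence[float], dropped_index: int) -> LccResult:
    """Insert the complement part ``1 - sum(retained)`` at ``dropped_index``.

    The completed vector is *not* forced onto the simplex: parts outside
    [0, 1] are possible for forecasted inputs and are flagged invalid
    rather than raised.
    """
    r = np.asarray(retained, dtype=float)
    D = r.size + 1
    if not 0 <= dropped_index < D:
        raise IndexError(f"dropped_index {dropped_index} out of range for D={D}")
    comp = 1.0 - r.sum()
    parts = np.insert(r, dropped_index, comp)
    valid = bool(np.all(parts >= 0.0) and np.all(parts <= 1.0))
    return LccResult(parts, valid, dropped_index)


def repair_lcc(
    parts: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    labels: tuple[str, ...] | None = None,
    context: str = "",
) -> Composition:
    """Clip an invalid LCC vector into [epsilon, 1] and re-close.

    Used at metric time so Aitchison distances stay defined; the raw
    flagged values are preserved upstream.
    """
    if np.any(parts < 0) or np.any(parts > 1):
        logger.warning("repairing out-of-range LCC composition %s", context)
    return closure(np.clip(parts, epsilon, 1.0), labels)


# ---------------------------------------------------------------------------
# Aitchison metrics
# ---------------------------------------------------------------------------

def _clr(x: Composition, epsilon: float | None) -> np.ndarray:
    p = replace_zeros(x, epsilon).parts
    lx = np.log(p)
    return lx - lx.mean()


def aitchison_distance(
    x: Composition, xhat: Composition, epsilon: float | None = DEFAULT_EPSILON
) -> float:
    """Aitchison distance: Euclidean distance between clr images.

    d_S(x, y) = || ln(x/gm(x)) - ln(y/gm(y)) ||_2.  Equals the Euclidean
    distance between the ILR coordinates of x and y (the ILR map is an
    isometry).
    """
    if x.D != xhat.D:
        raise ValueError(f"dimension mismatch: {x.D} vs {xhat.D}")
    return float(np.linalg.norm(_clr(x, epsilon) - _clr(xhat, epsilon)))


def coda_norm(x: Composition, epsilon: float | None = DEFAULT_EPSILON) -> float:
    """Aitchison norm ||x||_S = Euclidean norm of the clr vector.

    Equals the Aitchison distance from x to the uniform composition.
    """
    return float(np.linalg.norm(_clr(x, epsilon)))


def coda_errors(
    observed: CompositionSeries,
    predicted: CompositionSeries,
    epsilon: float | None = DEFAULT_EPSILON,
    root_mean_square: bool = False,
) -> tuple[float, float]:
    """CoDa-RMSE and CoDa-MAPE over aligned observed/predicted series.

    CoDa-RMSE is the arithmetic mean of the per-year Aitchison distances
    (the conventional definition in this setting, despite the name); set
    ``root_mean_square=True`` for a true root-mean-square of distances.
    CoDa-MAPE is the mean of distance / ||observed||_S, times 100.

    Raises ``ValueError`` when an observed composition is (numerically)
    uniform, whose zero Aitchison norm makes the MAPE undefined.
    """
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted lengths differ")
    if observed.years != predicted.years:
        raise ValueError("observed and predicted years are not aligned")
    dists = np.array(
        [
            aitchison_distance(o, p, epsilon)
            for o, p in zip(observed.values, predicted.values)
        ]
    )
    norms = np.array([coda_norm(o, epsilon) for o in observed.values])
    small = norms < 1e-12
    if small.any():
        year = observed.years[int(np.argmax(small))]
        raise ValueError(
            f"observed composition in {year} is uniform; CoDa-MAPE undefined"
        )
    rmse = float(np.sqrt(np.mean(dists**2)) if root_mean_square else dists.mean())
    mape = float(np.mean(dists / norms) * 100.0)
    return rmse, mape


def perturb(x: Composition, p: Composition) -> Composition:
    """Aitchison perturbation: closure of the elementwise product."""
    return closure(x.parts * p.parts, x.labels)
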