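"""Transforms, inverses and Aitchison metrics on the simplex."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codaf import (
    Composition,
    CompositionSeries,
    ConstraintError,
    HypersphericalAngles,
    IlrCoordinates,
    aitchison_distance,
    clamp_angles,
    closure,
    clr_from_ilr,
    coda_errors,
    coda_norm,
    drht_forward,
    drht_inverse,
    ilr_forward,
    ilr_inverse,
    lcc_complete,
    perturb,
    replace_zeros,
)

# strictly positive compositions of dimension 2..6
compositions = st.integers(2, 6).flatmap(
    lambda D: st.lists(st.floats(1e-4, 1.0), min_size=D, max_size=D)
).map(lambda parts: closure(np.array(parts)))


# ---------------------------------------------------------------------------
# closure and zero replacement
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw, expected",
    [
        ([2, 1, 1], [0.5, 0.25, 0.25]),
        ([0.5, 0.3, 0.2], [0.5, 0.3, 0.2]),
    ],
)
def test_closure_renormalises_proportionally(raw, expected):
    np.testing.assert_allclose(closure(raw).parts, expected, atol=1e-12)


@pytest.mark.parametrize("raw", [[0, 0, 0], [-0.1, 0.6, 0.5]])
def test_closure_rejects_degenerate_input(raw):
    with pytest.raises(ConstraintError):
        closure(raw)


def test_zero_replacement_preserves_unit_sum_and_ratios():
    x = Composition(np.array([0.0, 0.6, 0.4]))
    y = replace_zeros(x, 1e-6)
    assert y.parts[0] == pytest.approx(1e-6, rel=1e-6)
    assert y.parts.sum() == pytest.approx(1.0, abs=1e-12)
    assert y.parts[1] / y.parts[2] == pytest.approx(1.5, rel=1e-9)


def test_zero_replacement_disabled_raises():
    with pytest.raises(ConstraintError, match="index 0"):
        replace_zeros(Composition(np.array([0.0, 0.6, 0.4])), None)


# ---------------------------------------------------------------------------
# ILR pivot coordinates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "parts, expected",
    [
        ([1 / 3, 1 / 3, 1 / 3], [0.0, 0.0]),
        ([0.5, 0.25, 0.25], [0.490129, 0.282976]),
        ([0.8, 0.2], [0.980258]),  # sqrt(1/2) * ln 4
    ],
)
def test_ilr_forward_pivot_values(parts, expected):
    w = ilr_forward(closure(parts)).w
    np.testing.assert_allclose(w, expected, atol=1e-6)


@pytest.mark.parametrize(
    "w, expected",
    [
        ([0.0, 0.0], [1 / 3, 1 / 3, 1 / 3]),
        ([0.490129, 0.282976], [0.5, 0.25, 0.25]),
        ([0.980258], [0.8, 0.2]),
    ],
)
def test_ilr_inverse_values(w, expected):
    x = ilr_inverse(IlrCoordinates(np.array(w)))
    np.testing.assert_allclose(x.parts, expected, atol=1e-6)


@settings(max_examples=200, derandomize=True)
@given(compositions)
def test_ilr_round_trip(x):
    back = ilr_inverse(ilr_forward(x))
    np.testing.assert_allclose(back.parts, x.parts, atol=1e-10)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(-20, 20), min_size=1, max_size=5))
def test_clr_expansion_sums_to_zero(w):
    v = clr_from_ilr(IlrCoordinates(np.array(w))).v
    assert abs(v.sum()) < 1e-9


def test_non_finite_ilr_coordinates_rejected():
    with pytest.raises(ValueError):
        IlrCoordinates(np.array([np.nan, 0.0]))
    with pytest.raises(ValueError):
        IlrCoordinates(np.array([np.inf]))


# ---------------------------------------------------------------------------
# Hyperspherical transform
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "parts, expected",
    [
        ([0.25, 0.25, 0.5], [0.785398, 0.785398]),
        ([1 / 3, 1 / 3, 1 / 3], [0.785398, 0.955317]),
        ([0.0, 0.0, 1.0], [0.0, 0.0]),  # degenerate-denominator convention
    ],
)
def test_drht_forward_angles(parts, expected):
    x = Composition(np.array(parts))
    np.testing.assert_allclose(drht_forward(x).theta, expected, atol=1e-6)


@pytest.mark.parametrize(
    "theta, expected",
    [
        ([0.785398, 0.785398], [0.25, 0.25, 0.5]),
        ([0.0, 0.0], [0.0, 0.0, 1.0]),
        ([math.pi / 2, math.pi / 2], [1.0, 0.0, 0.0]),
    ],
)
def test_drht_inverse_values(theta, expected):
    x = drht_inverse(HypersphericalAngles(np.array(theta)))
    np.testing.assert_allclose(x.parts, expected, atol=1e-6)


@settings(max_examples=200, derandomize=True)
@given(compositions)
def test_drht_round_trip_and_exact_unit_sum(x):
    back = drht_inverse(drht_forward(x))
    np.testing.assert_allclose(back.parts, x.parts, atol=1e-10)
    assert abs(back.parts.sum() - 1.0) < 1e-12


def test_drht_round_trip_with_zero_parts():
    x = Composition(np.array([0.0, 0.3, 0.7]))
    back = drht_inverse(drht_forward(x))
    np.testing.assert_allclose(back.parts, x.parts, atol=1e-10)


def test_clamp_angles_clips_out_of_range_forecasts():
    t = clamp_angles(np.array([-0.2, 1.9]))
    assert t.theta[0] == 0.0
    assert t.theta[1] == pytest.approx(math.pi / 2)


# ---------------------------------------------------------------------------
# LCC completion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "retained, drop, expected, valid",
    [
        ([0.2, 0.7], 2, [0.2, 0.7, 0.1], True),
        ([0.6, 0.5], 2, [0.6, 0.5, -0.1], False),
        ([0.25, 0.5], 0, [0.25, 0.25, 0.5], True),
    ],
)
def test_lcc_complement_insertion_and_validity(retained, drop, expected, valid):
    res = lcc_complete(retained, drop)
    np.testing.assert_allclose(res.parts, expected, atol=1e-12)
    assert res.valid is valid


# ---------------------------------------------------------------------------
# Aitchison metrics
# ---------------------------------------------------------------------------

def test_aitchison_distance_worked_example():
    x = closure([0.5, 0.25, 0.25])
    y = closure([0.25, 0.25, 0.5])
    # clr difference is (ln2, 0, -ln2): distance ln2 * sqrt(2)
    assert aitchison_distance(x, y) == pytest.approx(math.log(2) * math.sqrt(2), abs=1e-12)


def test_coda_norm_worked_example():
    x = closure([0.5, 0.25, 0.25])
    # clr is (2/3, -1/3, -1/3) * ln2: norm ln2 * sqrt(2/3)
    assert coda_norm(x) == pytest.approx(math.log(2) * math.sqrt(2.0 / 3.0), abs=1e-12)
    assert coda_norm(closure([1, 1, 1])) == 0.0


@settings(max_examples=150, derandomize=True)
@given(compositions, compositions, compositions)
def test_metric_axioms(x, y, z):
    if not (x.D == y.D == z.D):
        return
    dxy = aitchison_distance(x, y)
    assert dxy >= 0
    assert dxy == pytest.approx(aitchison_distance(y, x), abs=1e-12)
    assert aitchison_distance(x, x) == pytest.approx(0.0, abs=1e-12)
    assert dxy <= aitchison_distance(x, z) + aitchison_distance(z, y) + 1e-10


@settings(max_examples=150, derandomize=True)
@given(compositions, compositions)
def test_ilr_isometry_oracle(x, y):
    """Aitchison distance equals Euclidean distance of ILR images."""
    if x.D != y.D:
        return
    euclid = float(np.linalg.norm(ilr_forward(x).w - ilr_forward(y).w))
    assert aitchison_distance(x, y) == pytest.approx(euclid, abs=1e-10)


@settings(max_examples=100, derandomize=True)
@given(compositions, compositions, compositions)
def test_perturbation_invariance(p, x, y):
    if not (p.D == x.D == y.D):
        return
    d0 = aitchison_distance(x, y)
    d1 = aitchison_distance(perturb(p, x), perturb(p, y))
    assert d1 == pytest.approx(d0, abs=1e-10)


def test_norm_equals_distance_to_uniform(random_composition):
    for _ in range(20):
        x = random_composition(D=4)
        u = closure(np.ones(4))
        assert coda_norm(x) == pytest.approx(aitchison_distance(x, u), abs=1e-12)


# ---------------------------------------------------------------------------
# CoDa error aggregates
# ---------------------------------------------------------------------------

def _series(rows, years=None):
    rows = np.atleast_2d(rows)
    years = years or range(2000, 2000 + len(rows))
    return CompositionSeries.from_matrix(years, rows)


def test_coda_errors_zero_for_perfect_forecast():
    obs = _series([[0.2, 0.5, 0.3], [0.25, 0.45, 0.3]])
    assert coda_errors(obs, obs) == (0.0, 0.0)


def test_coda_errors_single_point_worked_example():
    obs = _series([[0.5, 0.25, 0.25]])
    pred = _series([[0.25, 0.25, 0.5]])
    rmse, mape = coda_errors(obs, pred)
    assert rmse == pytest.approx(math.log(2) * math.sqrt(2), abs=1e-9)
    # distance / norm = sqrt(3), exactly
    assert mape == pytest.approx(100 * math.sqrt(3), abs=1e-6)


def test_coda_rmse_is_mean_of_distances(random_composition):
    obs = _series([random_composition().parts for _ in range(2)])
    pred = _series([random_composition().parts for _ in range(2)])
    d = [
        aitchison_distance(o, p) for o, p in zip(obs.values, pred.values)
    ]
    rmse, _ = coda_errors(obs, pred)
    assert rmse == pytest.approx(sum(d) / 2, abs=1e-12)
    rms, _ = coda_errors(obs, pred, root_mean_square=True)
    assert rms == pytest.approx(math.sqrt((d[0] ** 2 + d[1] ** 2) / 2), abs=1e-12)


def test_coda_mape_undefined_on_uniform_observation():
    obs = _series([[1 / 3, 1 / 3, 1 / 3]])
    pred = _series([[0.25, 0.25, 0.5]])
    with pytest.raises(ValueError, match="2000"):
        coda_errors(obs, pred)
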