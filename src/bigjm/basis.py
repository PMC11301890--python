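"""B-spline log baseline hazard, cumulative hazard and Kaplan-Meier.

The log baseline hazard is modelled as an intercept plus a clamped cubic
B-spline expansion over interior knots placed at quantiles of the observed
event times:

    log h0(t) = g0 + sum_q c_q B_q(t)

A clamped degree-d basis with Q interior knots has Q + d + 1 functions that
sum to one everywhere (partition of unity), which is collinear with the
intercept; the first basis function is therefore dropped, leaving Q + d free
spline coefficients. Evaluation beyond the boundary knots clamps t to the
boundary, so the log-hazard is constant outside the observed time range —
this keeps extrapolated hazards in dynamic prediction bounded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineBasis",
    "BaselineHazardCoefficients",
    "SurvivalCurve",
    "place_knots",
    "bspline_basis",
    "log_baseline_hazard",
    "cumulative_hazard",
    "integration_panels",
    "gauss_legendre_nodes",
    "kaplan_meier",
    "GL_NODES",
    "GL_WEIGHTS",
]

# 15-node Gauss-Legendre rule on [-1, 1], used for every hazard integral
GL_NODES, GL_WEIGHTS = np.polynomial.legendre.leggauss(15)


@dataclass(frozen=True)
class SplineBasis:
    """Clamped B-spline basis for the log baseline hazard."""

    interior_knots: tuple[float, ...]
    boundary: tuple[float, float]
    degree: int = 3

    def __post_init__(self):
        lo, hi = self.boundary
        if not lo < hi:
            raise ValueError(f"boundary must be increasing, got {self.boundary}")
        ks = np.asarray(self.interior_knots, dtype=float)
        if ks.size and (np.diff(ks) <= 0).any():
            raise ValueError("interior knots must be strictly increasing")
        if ks.size and (ks[0] <= lo or ks[-1] >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")

    @property
    def knot_vector(self) -> np.ndarray:
        """Full clamped knot vector (boundary knots repeated degree+1 times)."""
        lo, hi = self.boundary
        return np.concatenate(
            [
                np.full(self.degree + 1, lo),
                np.asarray(self.interior_knots, dtype=float),
                np.full(self.degree + 1, hi),
            ]
        )

    @property
    def n_basis(self) -> int:
        """Number of basis functions, Q + degree + 1."""
        return len(self.interior_knots) + self.degree + 1

    @property
    def n_free_coefs(self) -> int:
        """Spline coefficients actually estimated (first function dropped)."""
        return self.n_basis - 1


@dataclass(frozen=True)
class BaselineHazardCoefficients:
    """Intercept g0 and the free spline coefficients of log h0(t).

    ``spline_coefs`` multiplies basis functions 2..n_basis; the first basis
    function is absorbed into the intercept for identifiability.
    """

    intercept: float
    spline_coefs: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "spline_coefs", np.asarray(self.spline_coefs, dtype=float)
        )
        if not np.isfinite(self.intercept) or not np.isfinite(self.spline_coefs).all():
            raise ValueError("baseline hazard coefficients must be finite")


@dataclass(frozen=True)
class SurvivalCurve:
    """A non-increasing survival function tabulated on a time grid."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t) -> np.ndarray:
        """Right-continuous step evaluation, S(t) = 1 for t before the grid."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]

    def left_limit(self, t) -> np.ndarray:
        """Left-continuous evaluation S(t-)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]


def place_knots(event_times: np.ndarray, q: int, degree: int = 3) -> SplineBasis:
    """Place Q interior knots at event-time quantiles.

    Interior knots sit at the j/(Q+1) quantiles (j = 1..Q, linear/type-7
    interpolation) of the uncensored event times; the boundary spans
    (0, max(event_times)). At least Q + 2 distinct event times are required
    so the quantiles are meaningful.
    """
    times = np.asarray(event_times, dtype=float)
    if times.size == 0:
        raise ValueError("no event times supplied")
    if q < 0:
        raise ValueError("number of interior knots must be >= 0")
    distinct = np.unique(times)
    if distinct.size < q + 2:
        raise ValueError(
            f"need at least {q + 2} distinct event times for Q={q} interior "
            f"knots, got {distinct.size}"
        )
    hi = float(times.max())
    if q:
        probs = np.arange(1, q + 1) / (q + 1)
        knots = np.quantile(times, probs)  # linear interpolation = type 7
        knots = tuple(float(k) for k in knots)
    else:
        knots = ()
    return SplineBasis(interior_knots=knots, boundary=(0.0, hi), degree=degree)


def _clamp(t, basis: SplineBasis) -> np.ndarray:
    lo, hi = basis.boundary
    return np.clip(np.asarray(t, dtype=float), lo, hi)


def bspline_basis(t, basis: SplineBasis) -> np.ndarray:
    """All basis-function values at time(s) t, shape (..., n_basis).

    Times outside the boundary are clamped, so the basis (and hence the
    log-hazard) is constant beyond the boundary knots.
    """
    tc = _clamp(t, basis)
    flat = np.atleast_1d(tc).ravel()
    design = BSpline.design_matrix(
        flat, basis.knot_vector, basis.degree, extrapolate=False
    ).toarray()
    return design.reshape(np.shape(tc) + (basis.n_basis,))


def log_baseline_hazard(
    t, coefs: BaselineHazardCoefficients, basis: SplineBasis
) -> np.ndarray:
    """log h0(t) = intercept + spline_coefs . B_{2..}(t)."""
    b = bspline_basis(t, basis)
    return coefs.intercept + b[..., 1:] @ coefs.spline_coefs


def integration_panels(basis: SplineBasis, t0: float, t1: float) -> list[tuple[float, float]]:
    """Split [t0, t1] at spline knots (and the upper boundary).

    The log baseline hazard is a piecewise polynomial with kinks only at
    the knots, so per-panel Gauss-Legendre quadrature of the hazard is
    accurate to near machine precision.
    """
    cuts = [k for k in (*basis.interior_knots, basis.boundary[1]) if t0 < k < t1]
    edges = [t0, *sorted(cuts), t1]
    return list(zip(edges[:-1], edges[1:]))


def gauss_legendre_nodes(basis: SplineBasis, t0: float, t1: float):
    """Quadrature nodes and weights for [t0, t1], 15 per knot panel."""
    panels = integration_panels(basis, t0, t1)
    nodes, weights = [], []
    for a, b in panels:
        half = 0.5 * (b - a)
        nodes.append(0.5 * (a + b) + half * GL_NODES)
        weights.append(half * GL_WEIGHTS)
    return np.concatenate(nodes), np.concatenate(weights)


def cumulative_hazard(
    linear_predictor_fn,
    w_term: float,
    alpha: float,
    coefs: BaselineHazardCoefficients,
    basis: SplineBasis,
    t0: float,
    t1: float,
) -> float:
    """Integral of the subject hazard over [t0, t1].

    The hazard is h(s) = exp(log h0(s) + w_term + alpha * eta(s)) with
    ``linear_predictor_fn`` giving eta(s) (vectorised over s); 15-node
    Gauss-Legendre quadrature is applied on each knot panel of [t0, t1].
    """
    if t1 < t0:
        raise ValueError(f"t1={t1} < t0={t0}")
    if t1 == t0:
        return 0.0
    s, w = gauss_legendre_nodes(basis, t0, t1)
    logh = log_baseline_hazard(s, coefs, basis) + w_term
    eta = np.asarray(linear_predictor_fn(s), dtype=float)
    return float(np.sum(w * np.exp(logh + alpha * eta)))


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> SurvivalCurve:
    """Product-limit survival estimate from right-censored data.

    S(t) is the product over event times t_i <= t of (n_i - d_i)/n_i, with
    n_i the at-risk count just before t_i and d_i the events at t_i
    (right-continuous convention). Censored-only times leave the curve flat
    but shrink the risk set.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival data")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")

    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order].astype(int)
    uniq, start = np.unique(t_sorted, return_index=True)
    d = np.add.reduceat(e_sorted, start)  # events at each distinct time
    at_risk = times.size - start  # at risk just before each distinct time
    surv = np.cumprod((at_risk - d) / at_risk)
    return SurvivalCurve(times=uniq, survival=surv)
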