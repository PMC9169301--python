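"""Interval-wise similarity between two fitted risk curves.

The comparison window (the overlap of the two curves' supports inside the
half-yearly exam grid) is cut into the unit intervals (1,2), (2,3), ...,
(19,20), clipped to the overlap.  On each interval two L2 distances are
computed by Gauss-Legendre quadrature: the actual distance between the
curves, and the derived-function distance between their first derivatives
(trend discrepancy).  The influence factor theta blends the two, a decay
factor mu down-weights older intervals geometrically, and the decayed
aggregate is mapped to a similarity percentage used by the tiered
case-extraction strategy.

Because the blended quantity is a distance, a declared convention maps it to
[0,1]: each interval's blended distance c_i becomes s_i = exp(-c_i / s0)
for a scale s0 (zero distance -> similarity 1), and the decayed aggregate is
normalized by the total decay mass, Sim = sum_i s_i mu^(n-i) / sum_i
mu^(n-i).  The raw (unnormalized) decayed aggregate of the blended distances
is exposed alongside for direct checks of the formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import RiskCurve

__all__ = [
    "IncomparableCasesError",
    "SimilarityResult",
    "GRID_INTERVALS",
    "gauss_legendre_nodes",
    "actual_distance",
    "derivative_distance",
    "interval_combined",
    "decayed_aggregate",
    "distance_to_similarity",
    "pairwise_similarity",
]

#: the unit intervals of the 20-slot half-yearly exam grid
GRID_INTERVALS: tuple[tuple[int, int], ...] = tuple((j, j + 1) for j in range(1, 20))

_QUAD_NODES = 16


class IncomparableCasesError(ValueError):
    """The two cases share no time window; no similarity is defined."""


def gauss_legendre_nodes(lo: float, hi: float,
                         n: int = _QUAD_NODES) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes and weights scaled to the interval [lo, hi]."""
    x, w = np.polynomial.legendre.leggauss(n)
    half = 0.5 * (hi - lo)
    return lo + half * (x + 1.0), half * w


def _l2_interval(f: RiskCurve, g: RiskCurve, lo: float, hi: float,
                 use_delta: bool, length_normalized: bool,
                 n_nodes: int) -> float:
    for c in (f, g):
        a, b = c.effective_support if use_delta else c.support
        if lo < a - 1e-9 or hi > b + 1e-9:
            raise ValueError(
                f"interval [{lo}, {hi}] outside curve support [{a}, {b}]"
            )
    # composite rule split at the spline breakpoints, so the quadrature is
    # exact for the piecewise-polynomial integrand
    cuts = [lo, hi]
    for c in (f, g):
        shift = c.delta if use_delta else 0.0
        cuts.extend(k - shift for k in np.unique(c.knots) if lo < k - shift < hi)
    cuts = np.unique(cuts)
    integral = 0.0
    for a, b in zip(cuts, cuts[1:]):
        x, w = gauss_legendre_nodes(a, b, n_nodes)
        diff = f(x, use_delta=use_delta) - g(x, use_delta=use_delta)
        integral += float(w @ diff**2)
    if length_normalized:
        integral /= hi - lo
    return float(np.sqrt(max(integral, 0.0)))


def actual_distance(curve_a: RiskCurve, curve_b: RiskCurve,
                    interval: tuple[float, float], use_delta: bool = False,
                    length_normalized: bool = False,
                    n_nodes: int = _QUAD_NODES) -> float:
    """L2 distance between two risk curves over an interval.

    sqrt(int (R_a - R_b)^2 dt); with ``length_normalized`` the integral is
    divided by the interval length first (root-mean-square distance).
    """
    lo, hi = interval
    if hi <= lo:
        raise ValueError(f"empty interval {interval}")
    return _l2_interval(curve_a, curve_b, lo, hi, use_delta,
                        length_normalized, n_nodes)


def derivative_distance(curve_a: RiskCurve, curve_b: RiskCurve,
                        interval: tuple[float, float], use_delta: bool = False,
                        length_normalized: bool = False,
                        n_nodes: int = _QUAD_NODES) -> float:
    """L2 distance between the curves' first derivatives over an interval."""
    lo, hi = interval
    if hi <= lo:
        raise ValueError(f"empty interval {interval}")
    return _l2_interval(curve_a.derivative(), curve_b.derivative(), lo, hi,
                        use_delta, length_normalized, n_nodes)


def interval_combined(d_act: float, d_der: float, theta: float) -> float:
    """Blend of actual and derivative distance: theta*d_act + (1-theta)*d_der."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"influence factor theta must lie in [0, 1], got {theta}")
    return theta * d_act + (1.0 - theta) * d_der


def decayed_aggregate(interval_values, mu: float) -> float:
    """Geometric decay aggregation sum_i v_i * mu^(n-i) of time-ordered values.

    The most recent value has exponent zero (0^0 := 1), so mu = 0 keeps only
    the latest interval and mu = 1 is a plain sum.
    """
    v = np.asarray(interval_values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("need a non-empty 1-D sequence of interval values")
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"decay factor mu must lie in [0, 1], got {mu}")
    exponents = np.arange(len(v) - 1, -1, -1, dtype=float)
    return float(v @ np.power(mu, exponents))


def distance_to_similarity(combined: np.ndarray, s0: float = 1.0) -> np.ndarray:
    """Map nonnegative blended distances to (0, 1] similarities exp(-c/s0)."""
    if s0 <= 0:
        raise ValueError(f"similarity scale s0 must be positive, got {s0}")
    return np.exp(-np.asarray(combined, dtype=float) / s0)


@dataclass
class SimilarityResult:
    """Full per-interval breakdown of one pairwise comparison."""

    intervals: list[tuple[float, float]]
    d_act: np.ndarray
    d_der: np.ndarray
    combined: np.ndarray
    interval_similarities: np.ndarray
    theta: float
    mu: float
    s0: float
    raw_aggregate: float   # decayed aggregate of the blended distances, as printed
    similarity: float      # normalized decayed similarity in [0, 1]

    @property
    def percent(self) -> float:
        return 100.0 * self.similarity

    def to_dict(self) -> dict:
        return {
            "intervals": [list(iv) for iv in self.intervals],
            "d_act": self.d_act.tolist(),
            "d_der": self.d_der.tolist(),
            "combined": self.combined.tolist(),
            "interval_similarities": self.interval_similarities.tolist(),
            "theta": self.theta, "mu": self.mu, "s0": self.s0,
            "raw_aggregate": self.raw_aggregate,
            "similarity": self.similarity, "percent": self.percent,
        }


def overlap_intervals(curve_a: RiskCurve, curve_b: RiskCurve,
                      use_delta: bool = True,
                      min_length: float = 1e-9) -> list[tuple[float, float]]:
    """Unit grid intervals clipped to the curves' common support."""
    a0, a1 = curve_a.effective_support if use_delta else curve_a.support
    b0, b1 = curve_b.effective_support if use_delta else curve_b.support
    lo, hi = max(a0, b0), min(a1, b1)
    if hi - lo <= min_length:
        raise IncomparableCasesError(
            f"no overlapping support: [{a0:g}, {a1:g}] vs [{b0:g}, {b1:g}]"
        )
    out = []
    for j, j1 in GRID_INTERVALS:
        seg = (max(float(j), lo), min(float(j1), hi))
        if seg[1] - seg[0] > min_length:
            out.append(seg)
    return out


def pairwise_similarity(curve_a: RiskCurve, curve_b: RiskCurve,
                        theta: float = 0.6, mu: float = 0.8,
                        s0: float = 1.0, use_delta: bool = True,
                        n_nodes: int = _QUAD_NODES) -> SimilarityResult:
    """Compare two fitted risk curves over their common exam-grid window.

    Per clipped unit interval, length-normalized actual and derivative
    distances are blended with ``theta``; the blended distances are decayed
    with ``mu`` into the raw aggregate, and their exp(-c/s0) similarities
    into the normalized similarity (1.0 for identical curves).  Symmetric in
    its two arguments.  Raises :class:`IncomparableCasesError` when the
    supports do not overlap.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"influence factor theta must lie in [0, 1], got {theta}")
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"decay factor mu must lie in [0, 1], got {mu}")
    intervals = overlap_intervals(curve_a, curve_b, use_delta=use_delta)
    d_act = np.array([
        actual_distance(curve_a, curve_b, iv, use_delta=use_delta,
                        length_normalized=True, n_nodes=n_nodes)
        for iv in intervals
    ])
    d_der = np.array([
        derivative_distance(curve_a, curve_b, iv, use_delta=use_delta,
                            length_normalized=True, n_nodes=n_nodes)
        for iv in intervals
    ])
    combined = theta * d_act + (1.0 - theta) * d_der
    sims = distance_to_similarity(combined, s0)
    raw = decayed_aggregate(combined, mu)
    n = len(intervals)
    decay_mass = np.power(mu, np.arange(n - 1, -1, -1, dtype=float))
    similarity = float(sims @ decay_mass / decay_mass.sum())
    return SimilarityResult(
        intervals=intervals, d_act=d_act, d_der=d_der, combined=combined,
        interval_similarities=sims, theta=theta, mu=mu, s0=s0,
        raw_aggregate=raw, similarity=similarity,
    )
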