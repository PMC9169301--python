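"""Risk scoring and functional representation of risk trajectories.

Each examination's hypertension risk is the weighted sum of its attribute
codes.  A resident's time-ordered risk values are then smoothed into a
B-spline curve R(t) = sum_k c_k B_k(t) by least squares, and curves from
different residents can be aligned in time by a translation ("registration")
that shifts each curve toward the iteratively re-estimated cross-sectional
mean curve.

The B-spline basis is evaluated with the Cox-de Boor recursion: order-1
basis functions are interval indicators, and order-k functions are convex
blends of two order-(k-1) functions, with 0/0 terms taken as 0.  A spline
of order k has degree k-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "RiskSeries",
    "RiskCurve",
    "RegistrationResult",
    "risk_value",
    "risk_series",
    "bspline_basis",
    "fit_risk_curve",
    "register_curves",
]


# --------------------------------------------------------------------------
# risk scoring
# --------------------------------------------------------------------------

def risk_value(encoded: np.ndarray, weights) -> float:
    """Per-exam risk score: dot product of the code vector with the weights."""
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    x = np.asarray(encoded, dtype=float)
    if x.shape != w.shape:
        raise ValueError(
            f"dimension mismatch: encoded vector has length {x.shape}, "
            f"weights have length {w.shape}"
        )
    return float(x @ w)


@dataclass
class RiskSeries:
    """Time-ordered per-exam risk values for one resident."""

    resident_id: str
    times: np.ndarray
    risks: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.risks = np.asarray(self.risks, dtype=float)
        if self.times.shape != self.risks.shape or self.times.ndim != 1:
            raise ValueError("times and risks must be 1-D arrays of equal length")
        if len(self.times) == 0:
            raise ValueError("a risk series needs at least one examination")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("exam times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def tail(self, n: int) -> "RiskSeries":
        """The series restricted to its last ``n`` examinations."""
        n = min(n, len(self))
        return RiskSeries(self.resident_id, self.times[-n:], self.risks[-n:])


def risk_series(exams: Sequence, weights, resident_id: str | None = None) -> RiskSeries:
    """Score every exam of one resident and return the time-ordered series."""
    if len(exams) == 0:
        raise ValueError("need at least one exam record")
    ordered = sorted(exams, key=lambda e: e.exam_index)
    times = np.array([e.exam_index for e in ordered], dtype=float)
    risks = np.array([risk_value(e.encoded, weights) for e in ordered])
    rid = resident_id if resident_id is not None else ordered[0].resident_id
    return RiskSeries(rid, times, risks)


# --------------------------------------------------------------------------
# B-spline basis (Cox-de Boor)
# --------------------------------------------------------------------------

def bspline_basis(knots: np.ndarray, order: int, t) -> np.ndarray:
    """Evaluate all B-spline basis functions of the given order at ``t``.

    Returns an array of shape (K,) for scalar ``t`` or (len(t), K) for array
    input, with K = len(knots) - order.  The basis is right-continuous with
    the last non-empty knot span closed on the right, so the partition of
    unity holds on the whole closed span for clamped knot vectors.
    """
    knots = np.asarray(knots, dtype=float)
    scalar = np.isscalar(t) or np.ndim(t) == 0
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(np.diff(knots) < 0):
        raise ValueError("knots must be nondecreasing")
    if order < 1:
        raise ValueError("spline order must be >= 1")
    m = len(knots)
    K = m - order
    if K < 1:
        raise ValueError(f"need at least order+1={order + 1} knots, got {m}")
    if np.any(tt < knots[0]) or np.any(tt > knots[-1]):
        raise ValueError("evaluation point outside the knot span")

    # order 1: indicator of [tau_i, tau_{i+1}); close the final span on the right
    B = np.zeros((len(tt), m - 1))
    spans = np.diff(knots) > 0
    for i in np.nonzero(spans)[0]:
        B[:, i] = (knots[i] <= tt) & (tt < knots[i + 1])
    last = int(np.nonzero(spans)[0][-1]) if spans.any() else 0
    B[tt == knots[-1], last] = 1.0

    for k in range(2, order + 1):
        nb = m - k
        Bn = np.zeros((len(tt), nb))
        for i in range(nb):
            acc = np.zeros(len(tt))
            d1 = knots[i + k - 1] - knots[i]
            if d1 > 0:
                acc += (tt - knots[i]) / d1 * B[:, i]
            d2 = knots[i + k] - knots[i + 1]
            if d2 > 0:
                acc += (knots[i + k] - tt) / d2 * B[:, i + 1]
            Bn[:, i] = acc
        B = Bn
    return B[0] if scalar else B


@dataclass
class RiskCurve:
    """A fitted B-spline risk trajectory.

    ``delta`` is the time translation assigned by registration: the
    registered curve is R*(t) = R(t + delta), so its effective support is
    the spline support shifted by -delta.
    """

    knots: np.ndarray
    order: int
    coef: np.ndarray
    delta: float = 0.0
    resident_id: str = ""
    smsse: float = float("nan")

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.coef = np.asarray(self.coef, dtype=float)
        K = len(self.knots) - self.order
        if len(self.coef) != K:
            raise ValueError(
                f"coefficient count {len(self.coef)} != #knots - order = {K}"
            )

    @property
    def support(self) -> tuple[float, float]:
        """The raw spline support [first knot, last knot]."""
        return float(self.knots[0]), float(self.knots[-1])

    @property
    def effective_support(self) -> tuple[float, float]:
        """Where the registered curve R(t + delta) is defined."""
        a, b = self.support
        return a - self.delta, b - self.delta

    def __call__(self, t, use_delta: bool = False) -> np.ndarray:
        """Evaluate the curve (optionally as the registered R(t + delta))."""
        tt = np.asarray(t, dtype=float) + (self.delta if use_delta else 0.0)
        return bspline_basis(self.knots, self.order, tt) @ self.coef

    def eval_clamped(self, t, use_delta: bool = True) -> np.ndarray:
        """Evaluate with the argument clamped to the support (constant tails)."""
        tt = np.asarray(t, dtype=float) + (self.delta if use_delta else 0.0)
        a, b = self.support
        return bspline_basis(self.knots, self.order, np.clip(tt, a, b)) @ self.coef

    def derivative(self) -> "RiskCurve":
        """The first derivative R'(t), itself a spline of order-1 lower.

        Order-1 (piecewise constant) curves have an identically zero
        derivative, returned as a zero-coefficient curve on the same knots.
        """
        if self.order == 1:
            return replace(self, coef=np.zeros_like(self.coef))
        k, tau, c = self.order, self.knots, self.coef
        K = len(c)
        dcoef = np.zeros(K - 1)
        for i in range(K - 1):
            denom = tau[i + k] - tau[i + 1]
            if denom > 0:
                dcoef[i] = (k - 1) * (c[i + 1] - c[i]) / denom
        return RiskCurve(
            knots=tau[1:-1], order=k - 1, coef=dcoef,
            delta=self.delta, resident_id=self.resident_id,
        )

    def to_dict(self) -> dict:
        return {
            "resident_id": self.resident_id,
            "knots": self.knots.tolist(),
            "order": self.order,
            "coefficients": self.coef.tolist(),
            "support": list(self.support),
            "delta": self.delta,
            "smsse": None if np.isnan(self.smsse) else self.smsse,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskCurve":
        return cls(
            knots=np.asarray(d["knots"], dtype=float),
            order=int(d["order"]),
            coef=np.asarray(d["coefficients"], dtype=float),
            delta=float(d.get("delta", 0.0)),
            resident_id=str(d.get("resident_id", "")),
            smsse=float("nan") if d.get("smsse") is None else float(d["smsse"]),
        )


# --------------------------------------------------------------------------
# least-squares smoothing
# --------------------------------------------------------------------------

def _clamped_knots(times: np.ndarray, order: int, n_basis: int,
                   interpolating: bool) -> np.ndarray:
    """Clamped knot vector with ``n_basis - order`` interior knots.

    Interpolating fits use de Boor's knot-averaging rule (interior knot j is
    the mean of order-1 consecutive interior data times), which satisfies
    the Schoenberg-Whitney conditions; smoothing fits place interior knots
    at equally spaced quantiles of the observed times.
    """
    n_interior = n_basis - order
    t0, t1 = times[0], times[-1]
    if n_interior <= 0:
        interior = np.empty(0)
    elif interpolating:
        interior = np.array([
            times[j:j + order - 1].mean() for j in range(1, n_interior + 1)
        ])
    else:
        qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        interior = np.quantile(times, qs)
    return np.concatenate([np.full(order, t0), interior, np.full(order, t1)])


def fit_risk_curve(series: RiskSeries, order: int = 4,
                   knots: str | int = "auto",
                   max_basis: int = 6) -> RiskCurve:
    """Least-squares B-spline fit of a risk series.

    The objective is the sum of squared residuals at the exam times,
    SMSSE = sum_j (risk_j - sum_k c_k B_k(t_j))^2, minimized over the
    coefficients.  The achieved SMSSE is stored on the returned curve.

    ``knots`` selects the basis size K: "auto" uses roughly one basis
    function per two observations, K = min(``max_basis``, ceil(N/2)),
    lowering the order to K when needed — noisy exam data is never
    interpolated and short series get deliberately stiff fits;
    "interpolating" uses K = N (the fit then reproduces the data); an
    integer requests that K directly.  Series shorter than the requested
    order fall back to order N.
    """
    N = len(series)
    if N == 1:
        # degenerate one-point series: constant at that point
        t0 = series.times[0]
        return RiskCurve(
            knots=np.array([t0, t0]), order=1,
            coef=np.array([series.risks[0]]),
            resident_id=series.resident_id, smsse=0.0,
        )
    order = max(1, min(order, N))
    if knots == "auto":
        n_basis = min(max_basis, max(2, (N + 1) // 2))
        order = min(order, n_basis)
    elif knots == "interpolating":
        n_basis = N
    elif isinstance(knots, (int, np.integer)):
        n_basis = int(knots)
    else:
        raise ValueError(f"unknown knot strategy {knots!r}")
    n_basis = max(n_basis, order)
    if n_basis > N:
        raise ValueError(
            f"underdetermined fit: {n_basis} basis functions but only {N} "
            f"observations; reduce the spline order or the number of knots"
        )

    tau = _clamped_knots(series.times, order, n_basis,
                         interpolating=(n_basis == N))
    A = bspline_basis(tau, order, series.times)
    coef, _, _, _ = np.linalg.lstsq(A, series.risks, rcond=None)
    resid = series.risks - A @ coef
    return RiskCurve(
        knots=tau, order=order, coef=coef,
        resident_id=series.resident_id, smsse=float(resid @ resid),
    )


# --------------------------------------------------------------------------
# registration (translation alignment)
# --------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    """Output of translation registration of a set of risk curves."""

    curves: list[RiskCurve]
    deltas: np.ndarray
    regsse: list[float] = field(default_factory=list)
    converged: bool = False
    window: tuple[float, float] = (0.0, 0.0)


def register_curves(curves: Sequence[RiskCurve], max_shift: float = 2.0,
                    tol: float = 1e-6, max_iter: int = 50,
                    n_grid: int = 201) -> RegistrationResult:
    """Align curves in time by per-curve translations toward the mean curve.

    Alternating minimization of REGSSE = sum_i int [R_i(t + d_i) - mu(t)]^2 dt
    over the common support window: the mean curve mu is re-estimated from
    the currently shifted curves, then each d_i is optimized on
    [-max_shift, max_shift] and accepted only if it strictly lowers that
    curve's integral, so REGSSE never increases.  Shifted curves are
    evaluated with constant extrapolation at their support edges, keeping
    the integration window fixed across iterations.  Iteration stops when
    the mean curve changes by less than ``tol`` (sup-norm) or after
    ``max_iter`` sweeps.
    """
    if len(curves) < 2:
        raise ValueError("registration needs at least two curves")
    lo = max(c.support[0] for c in curves)
    hi = min(c.support[1] for c in curves)
    if hi - lo <= 0:
        raise ValueError("curves have no common support window to register on")

    grid = np.linspace(lo, hi, n_grid)
    # dense presample of each raw curve (clamped beyond its support) so that
    # shifted evaluations are cheap linear interpolations
    tfine = np.linspace(lo - max_shift, hi + max_shift, 2001)
    samples = [c.eval_clamped(tfine, use_delta=False) for c in curves]

    def shifted(i: int, d: float) -> np.ndarray:
        return np.interp(grid + d, tfine, samples[i])

    deltas = np.zeros(len(curves))
    vals = np.array([shifted(i, 0.0) for i in range(len(curves))])
    mean = vals.mean(axis=0)
    history: list[float] = []
    converged = False

    for _ in range(max_iter):
        history.append(float(np.trapezoid((vals - mean) ** 2, grid, axis=1).sum()))
        for i in range(len(curves)):
            f = lambda d: float(np.trapezoid((shifted(i, d) - mean) ** 2, grid))
            res = minimize_scalar(f, bounds=(-max_shift, max_shift), method="bounded")
            if res.fun < f(deltas[i]) - 1e-12:
                deltas[i] = float(res.x)
                vals[i] = shifted(i, deltas[i])
        new_mean = vals.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            converged = True
            break
        mean = new_mean
    history.append(float(np.trapezoid((vals - mean) ** 2, grid, axis=1).sum()))

    registered = [replace(c, delta=float(d)) for c, d in zip(curves, deltas)]
    return RegistrationResult(
        curves=registered, deltas=deltas, regsse=history,
        converged=converged, window=(float(lo), float(hi)),
    )
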