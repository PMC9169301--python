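"""Case base, retrieval, tiered reuse, and the synthetic evaluation harness.

Retrieval ranks the stored cases by the decayed interval similarity of
their fitted risk curves against the target's curve, then applies the
tiered case-extraction strategy: above 90% similarity the source protocol
is reused directly, 70-90% makes it an alternative plan, 60-70% an
auxiliary reference, and at or below 60% the retrieved case is not used.

Two latest-exam baselines are provided for benchmarking: cosine similarity
of the encoded attribute vectors, and a simplified grey-relational score
(resolution coefficient 0.5).  Both are declared stand-ins for the
cross-sectional comparators in the literature, not reimplementations; they
see only the most recent examination, so their accuracy cannot improve with
the length of the target's history.

The evaluation harness replays the retrieval experiment on a synthetic
cohort: a retrieval is "correct" when the top-ranked case lies in the
target's ground-truth top-k neighbour list (the generator's latent-curve
oracle standing in for the panel of physicians, k = 10 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import RiskCurve, RiskSeries, fit_risk_curve, register_curves, risk_series
from .encoding import Cohort
from .similarity import GRID_INTERVALS, gauss_legendre_nodes
from .simulate import SyntheticCohort
from .weights import WeightVector, fit_forest_weights

__all__ = [
    "Case",
    "CaseBase",
    "RetrievalOutcome",
    "extract_tier",
    "retrieve",
    "cosine_scores",
    "grey_relational_scores",
    "Evaluator",
    "evaluate_accuracy",
    "sweep_parameters",
]


# --------------------------------------------------------------------------
# tiered case-extraction strategy
# --------------------------------------------------------------------------

def extract_tier(similarity_pct: float) -> str:
    """Map a similarity percentage to the reuse tier of the best case."""
    if not 0.0 <= similarity_pct <= 100.0:
        raise ValueError(
            f"similarity percentage must lie in [0, 100], got {similarity_pct}"
        )
    if similarity_pct > 90.0:
        return "reuse"
    if similarity_pct > 70.0:
        return "alternative"
    if similarity_pct > 60.0:
        return "auxiliary"
    return "none"


# --------------------------------------------------------------------------
# fast interval-distance kernel on a fixed quadrature grid
# --------------------------------------------------------------------------

class _QuadGrid:
    """Gauss-Legendre nodes of every unit interval of the exam grid."""

    def __init__(self, n_nodes: int = 16):
        nodes, w = gauss_legendre_nodes(0.0, 1.0, n_nodes)
        self.n_nodes = n_nodes
        self.weights = w                                    # unit-length weights
        self.nodes = np.concatenate([j + nodes for j, _ in GRID_INTERVALS])
        self.n_intervals = len(GRID_INTERVALS)

    def row(self, curve: RiskCurve) -> tuple[np.ndarray, np.ndarray]:
        """Curve and derivative values at every node; NaN outside support."""
        a, b = curve.effective_support
        inside = (self.nodes >= a) & (self.nodes <= b)
        vals = np.full(self.nodes.shape, np.nan)
        dvals = np.full(self.nodes.shape, np.nan)
        if inside.any():
            t = self.nodes[inside]
            vals[inside] = curve(t, use_delta=True)
            dvals[inside] = curve.derivative()(t, use_delta=True)
        return vals, dvals


def _interval_distances(trow: tuple[np.ndarray, np.ndarray],
                        rows: tuple[np.ndarray, np.ndarray],
                        grid: _QuadGrid) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval RMS distances of one target row against stacked rows.

    Returns (D_act, D_der), each (n_cases, 19), NaN where a unit interval is
    not fully inside both supports.
    """
    tv, td = trow
    vals, dvals = rows
    k, m = grid.n_intervals, grid.n_nodes
    dv = (vals - tv).reshape(-1, k, m)
    dd = (dvals - td).reshape(-1, k, m)
    with np.errstate(invalid="ignore"):
        D_act = np.sqrt(np.einsum("nkm,m->nk", dv * dv, grid.weights))
        D_der = np.sqrt(np.einsum("nkm,m->nk", dd * dd, grid.weights))
    return D_act, D_der


def _decayed_percent(D_act: np.ndarray, D_der: np.ndarray, theta: float,
                     mu: float, s0: float | None = None
                     ) -> tuple[np.ndarray, float]:
    """Similarity percentages from per-interval distance matrices.

    Rows without any comparable interval come back NaN.  When ``s0`` is not
    given it is set to the median positive blended distance over all rows
    (1.0 if there is none), so the scale adapts to the case base.
    """
    C = theta * D_act + (1.0 - theta) * D_der
    mask = np.isfinite(C)
    if s0 is None:
        pos = C[mask & (C > 0)]
        s0 = float(np.median(pos)) if pos.size else 1.0
    S = np.where(mask, np.exp(-np.where(mask, C, 0.0) / s0), 0.0)
    # geometric decay over each row's comparable intervals, newest first
    after = np.cumsum(mask[:, ::-1], axis=1)[:, ::-1] - mask
    decay = np.where(mask, np.power(float(mu), after.astype(float)), 0.0)
    mass = decay.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * (S * decay).sum(axis=1) / mass
    pct[mass == 0] = np.nan
    return pct, s0


# --------------------------------------------------------------------------
# case base and retrieval
# --------------------------------------------------------------------------

@dataclass
class Case:
    """One stored source case: fitted curve, exam metadata, opaque protocol."""

    case_id: str
    curve: RiskCurve
    series: RiskSeries
    latest_encoded: np.ndarray
    last_exam: float
    protocol: object = None


class CaseBase:
    """Stored source cases with precomputed quadrature rows for retrieval."""

    def __init__(self, cases: Sequence[Case], n_nodes: int = 16):
        self.cases: dict[str, Case] = {}
        for c in cases:
            if c.case_id in self.cases:
                raise ValueError(f"duplicate case id {c.case_id!r}")
            self.cases[c.case_id] = c
        self._grid = _QuadGrid(n_nodes)
        rows = [self._grid.row(c.curve) for c in self.cases.values()]
        self._vals = np.array([r[0] for r in rows])
        self._dvals = np.array([r[1] for r in rows])

    def __len__(self) -> int:
        return len(self.cases)

    def __contains__(self, case_id: str) -> bool:
        return case_id in self.cases

    def ids(self) -> list[str]:
        return list(self.cases)

    @classmethod
    def from_cohort(cls, cohort: Cohort, weights: WeightVector,
                    order: int = 4, max_basis: int = 6,
                    register: bool = True,
                    protocols: dict | None = None) -> "CaseBase":
        """Fit one risk curve per resident and assemble the case base.

        With ``register`` on (the default), all curves are first aligned by
        translation registration; the stored curves carry their shifts.
        """
        cases = []
        curves = []
        for rid in cohort.ids():
            exams = cohort.exams(rid)
            series = risk_series(exams, weights)
            curves.append(fit_risk_curve(series, order=order, max_basis=max_basis))
            cases.append(Case(
                case_id=rid, curve=curves[-1], series=series,
                latest_encoded=np.asarray(exams[-1].encoded, dtype=float),
                last_exam=float(exams[-1].exam_index),
                protocol=None if protocols is None else protocols.get(rid),
            ))
        if register and len(curves) >= 2:
            reg = register_curves(curves)
            for case, registered in zip(cases, reg.curves):
                case.curve = registered
        return cls(cases)


@dataclass
class RetrievalOutcome:
    """Ranked retrieval result plus the reuse tier of the best case."""

    ranked: list[tuple[str, float]]
    tier: str
    n_incomparable: int
    s0: float
    best_protocol: object = None

    @property
    def best(self) -> tuple[str, float] | None:
        return self.ranked[0] if self.ranked else None


def _rank(pct: np.ndarray, ids: list[str], last: np.ndarray,
          k: int | None) -> tuple[list[tuple[str, float]], int]:
    finite = np.isfinite(pct)
    order = sorted(
        np.nonzero(finite)[0],
        key=lambda i: (-pct[i], -last[i], ids[i]),
    )
    ranked = [(ids[i], float(pct[i])) for i in order]
    if k is not None:
        ranked = ranked[:k]
    return ranked, int((~finite).sum())


def retrieve(target: Case | RiskCurve | str, base: CaseBase,
             theta: float = 0.6, mu: float = 0.8,
             k: int | None = None, s0: float | None = None,
             exclude_self: bool = True) -> RetrievalOutcome:
    """Rank the case base against a target and tier the best case.

    ``target`` may be a Case, a bare fitted curve, or the id of a stored
    case (which is then excluded from its own ranking unless
    ``exclude_self`` is off).  Cases whose support does not overlap the
    target's are excluded and counted as incomparable.  Ties are broken in
    favour of the more recently examined case, then by id.
    """
    if len(base) == 0:
        raise ValueError("case base is empty")
    self_id = None
    if isinstance(target, str):
        if target not in base:
            raise KeyError(f"unknown case id {target!r}")
        if exclude_self:
            self_id = target
        target_curve = base.cases[target].curve
    elif isinstance(target, Case):
        target_curve = target.curve
        if exclude_self and target.case_id in base:
            self_id = target.case_id
    else:
        target_curve = target
    trow = base._grid.row(target_curve)
    D_act, D_der = _interval_distances(trow, (base._vals, base._dvals), base._grid)
    pct, s0_used = _decayed_percent(D_act, D_der, theta, mu, s0)
    ids = base.ids()
    if self_id is not None:
        pct[ids.index(self_id)] = np.nan
    last = np.array([base.cases[i].last_exam for i in ids])
    ranked, n_bad = _rank(pct, ids, last, k)
    if self_id is not None:
        n_bad -= 1
    if not ranked:
        return RetrievalOutcome(ranked=[], tier="none", n_incomparable=n_bad,
                                s0=s0_used)
    tier = extract_tier(ranked[0][1])
    best_protocol = base.cases[ranked[0][0]].protocol if tier == "reuse" else None
    return RetrievalOutcome(ranked=ranked, tier=tier, n_incomparable=n_bad,
                            s0=s0_used, best_protocol=best_protocol)


# --------------------------------------------------------------------------
# latest-exam baselines
# --------------------------------------------------------------------------

def cosine_scores(target_vec: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Cosine similarity of the target's latest exam vector to each row."""
    x = np.asarray(target_vec, dtype=float)
    M = np.asarray(matrix, dtype=float)
    nx = np.linalg.norm(x)
    nr = np.linalg.norm(M, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = M @ x / (nr * nx)
    return np.where(np.isfinite(s), s, 0.0)


def grey_relational_scores(target_vec: np.ndarray, matrix: np.ndarray,
                           resolution: float = 0.5) -> np.ndarray:
    """Mean grey-relational coefficient of each row against the target."""
    x = np.asarray(target_vec, dtype=float)
    M = np.asarray(matrix, dtype=float)
    delta = np.abs(M - x)
    dmin, dmax = delta.min(), delta.max()
    if dmax == 0:
        return np.ones(len(M))
    gamma = (dmin + resolution * dmax) / (delta + resolution * dmax)
    return gamma.mean(axis=1)


# --------------------------------------------------------------------------
# synthetic evaluation harness
# --------------------------------------------------------------------------

class Evaluator:
    """Replays the retrieval-accuracy experiment on a synthetic cohort.

    Fits attribute weights (unless given), one risk curve per resident, and
    precomputes the quadrature rows once; individual accuracy queries for
    any (theta, mu), retrieval method, or truncated target history then
    reuse the cached distances.  Targets are compared in the raw exam-time
    frame (no registration), since truncated target histories have no
    consistent registration.
    """

    def __init__(self, syn: SyntheticCohort, weights: WeightVector | None = None,
                 order: int = 4, max_basis: int = 6,
                 forest_depth: int = 5, forest_trees: int = 500, seed: int = 0):
        self.syn = syn
        cohort = syn.cohort
        self.weights = weights if weights is not None else fit_forest_weights(
            cohort, depth=forest_depth, n_trees=forest_trees, seed=seed)
        self.order = order
        self.max_basis = max_basis
        self.ids = cohort.ids()
        self._index = {rid: i for i, rid in enumerate(self.ids)}
        self.series = {rid: risk_series(cohort.exams(rid), self.weights)
                       for rid in self.ids}
        self.curves = {rid: fit_risk_curve(s, order=order, max_basis=max_basis)
                       for rid, s in self.series.items()}
        self._grid = _QuadGrid()
        rows = [self._grid.row(self.curves[rid]) for rid in self.ids]
        self._vals = np.array([r[0] for r in rows])
        self._dvals = np.array([r[1] for r in rows])
        self.latest = np.array([
            cohort.exams(rid)[-1].encoded for rid in self.ids])
        self.last_time = np.array([
            cohort.exams(rid)[-1].exam_index for rid in self.ids], dtype=float)
        self._dist_cache: dict = {}

    # -- target handling --------------------------------------------------
    def select_targets(self, n_targets: int, seed: int = 0,
                       min_exams: int = 2) -> list[str]:
        eligible = [rid for rid in self.ids if len(self.series[rid]) >= min_exams]
        if n_targets > len(eligible):
            raise ValueError(
                f"requested {n_targets} targets but only {len(eligible)} "
                f"residents have >= {min_exams} exams"
            )
        rng = np.random.default_rng(seed)
        picked = rng.choice(len(eligible), size=n_targets, replace=False)
        return [eligible[i] for i in sorted(picked)]

    def _target_distances(self, rid: str, exam_count: int | None
                          ) -> tuple[np.ndarray, np.ndarray]:
        key = (rid, exam_count)
        if key not in self._dist_cache:
            if exam_count is None:
                curve = self.curves[rid]
            else:
                curve = fit_risk_curve(self.series[rid].tail(exam_count),
                                       order=self.order, max_basis=self.max_basis)
            trow = self._grid.row(curve)
            self._dist_cache[key] = _interval_distances(
                trow, (self._vals, self._dvals), self._grid)
        return self._dist_cache[key]

    def _top1(self, pct: np.ndarray, self_idx: int) -> int | None:
        pct = pct.copy()
        pct[self_idx] = np.nan
        finite = np.nonzero(np.isfinite(pct))[0]
        if finite.size == 0:
            return None
        return min(finite, key=lambda i: (-pct[i], -self.last_time[i], self.ids[i]))

    # -- accuracy queries -------------------------------------------------
    def accuracies(self, targets: Sequence[str],
                   params: Sequence[tuple[float, float]],
                   exam_count: int | None = None,
                   k_truth: int = 10) -> np.ndarray:
        """Top-1-in-top-k accuracy for each (theta, mu) pair at once."""
        hits = np.zeros(len(params))
        for rid in targets:
            D_act, D_der = self._target_distances(rid, exam_count)
            truth = set(self.syn.ground_truth_topk(rid, k_truth).ids)
            for p, (theta, mu) in enumerate(params):
                pct, _ = _decayed_percent(D_act, D_der, theta, mu)
                top = self._top1(pct, self._index[rid])
                if top is not None and self.ids[top] in truth:
                    hits[p] += 1
        return hits / len(targets)

    def accuracy(self, targets: Sequence[str], theta: float = 0.6,
                 mu: float = 0.8, exam_count: int | None = None,
                 k_truth: int = 10) -> float:
        return float(self.accuracies(targets, [(theta, mu)], exam_count,
                                     k_truth)[0])

    def baseline_accuracy(self, targets: Sequence[str], method: str,
                          k_truth: int = 10, seed: int = 0) -> float:
        """Accuracy of a latest-exam baseline ('cosine', 'gra', 'random')
        or of the latent-curve oracle ('latent')."""
        rng = np.random.default_rng(seed)
        hits = 0
        for rid in targets:
            i = self._index[rid]
            truth = set(self.syn.ground_truth_topk(rid, k_truth).ids)
            if method == "cosine":
                s = cosine_scores(self.latest[i], self.latest)
            elif method == "gra":
                s = grey_relational_scores(self.latest[i], self.latest)
            elif method == "random":
                s = rng.random(len(self.ids))
            elif method == "latent":
                lo, hi = self.syn.observed_support(rid)
                dense = np.linspace(lo, hi, 64)
                mine = self.syn.latent_on(rid, dense)
                diffs = np.array([
                    np.trapezoid((self.syn.latent_on(r, dense) - mine) ** 2, dense)
                    for r in self.ids])
                s = -diffs
            else:
                raise ValueError(f"unknown baseline method {method!r}")
            s = s.astype(float)
            s[i] = -np.inf
            top = min(range(len(s)),
                      key=lambda j: (-s[j], -self.last_time[j], self.ids[j]))
            hits += self.ids[top] in truth
        return hits / len(targets)


def evaluate_accuracy(syn: SyntheticCohort, theta: float = 0.6, mu: float = 0.8,
                      n_targets: int = 100, k_truth: int = 10, seed: int = 0,
                      exam_count: int | None = None,
                      weights: WeightVector | None = None) -> float:
    """One-shot retrieval accuracy of the curve-based method on a cohort."""
    ev = Evaluator(syn, weights=weights, seed=seed)
    min_exams = 2 if exam_count is None else max(2, exam_count)
    targets = ev.select_targets(n_targets, seed=seed, min_exams=min_exams)
    return ev.accuracy(targets, theta=theta, mu=mu, exam_count=exam_count,
                       k_truth=k_truth)


def sweep_parameters(syn: SyntheticCohort,
                     theta_grid: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                     mu_grid: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                     exam_counts: Sequence[int] = (2, 4, 6, 8, 10),
                     n_targets: int = 100, k_truth: int = 10, seed: int = 0,
                     theta: float = 0.6, mu: float = 0.8,
                     weights: WeightVector | None = None) -> pd.DataFrame:
    """Accuracy sweeps over theta, mu, and the target's history length.

    The exam-count sweep also runs the cosine and grey-relational
    latest-exam baselines.  Returns a tidy frame with columns
    (dimension, value, method, accuracy).
    """
    if not (len(theta_grid) and len(mu_grid) and len(exam_counts)):
        raise ValueError("all sweep grids must be non-empty")
    ev = Evaluator(syn, weights=weights, seed=seed)
    min_exams = max(2, max(exam_counts))
    targets = ev.select_targets(n_targets, seed=seed, min_exams=min_exams)
    rows = []
    acc = ev.accuracies(targets, [(th, mu) for th in theta_grid])
    rows += [("theta", th, "fda_cbr", a) for th, a in zip(theta_grid, acc)]
    acc = ev.accuracies(targets, [(theta, m) for m in mu_grid])
    rows += [("mu", m, "fda_cbr", a) for m, a in zip(mu_grid, acc)]
    for m in exam_counts:
        a = ev.accuracy(targets, theta=theta, mu=mu, exam_count=int(m),
                        k_truth=k_truth)
        rows.append(("exam_count", m, "fda_cbr", a))
    for method in ("cosine", "gra"):
        a = ev.baseline_accuracy(targets, method, k_truth=k_truth, seed=seed)
        rows += [("exam_count", m, f"{method}_cbr", a) for m in exam_counts]
    return pd.DataFrame(rows, columns=["dimension", "value", "method", "accuracy"])
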