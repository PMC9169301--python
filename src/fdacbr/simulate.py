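"""Synthetic community-examination cohorts with planted trajectory structure.

Real community screening data cannot be redistributed, so every downstream
stage is exercised on cohorts generated here.  The generator plants the
statistical structure the retrieval method assumes:

* each resident belongs to one of a few *trajectory archetypes* (e.g.
  steadily worsening, stable, improving); the resident's latent risk
  trajectory is the archetype shape plus an individual level offset and a
  smooth piecewise-linear perturbation;
* residents attend the half-yearly examinations irregularly (each exam is
  kept independently with the attendance probability);
* at each attended exam, the ten clinical/lifestyle attributes that change
  over time (BMI, exercise, blood lipids, ...) are quantized from a noisy
  copy of the latent severity, so the weighted code sum tracks the latent
  trajectory; demographic attributes (gender, age band, diet, smoking,
  drinking, heart rhythm) are drawn once per resident from population
  frequencies, independent of the trajectory — static confounders the
  similarity method has to be robust to;
* the hypertension label is Bernoulli with probability increasing in the
  latent risk.

Ground truth for retrieval is defined on the noise-free latent curves: the
correct neighbours of a target are the same-archetype residents closest in
L2 distance between latent trajectories over the target's observed window.
Any similarity method that sees only the noisy discretized exams can at
best approach this oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .encoding import (
    Cohort,
    CategoricalAttribute,
    EncodingScheme,
    ExamRecord,
    RangeAttribute,
    default_scheme,
)

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "TopK",
    "simulate_cohort",
    "simulate_single_signal_cohort",
    "ground_truth_topk",
]


@dataclass
class SimConfig:
    """Generator settings; the seed fully determines the output cohort."""

    n_residents: int = 500
    grid_length: int = 20
    attendance_prob: float = 0.8
    n_archetypes: int = 3
    noise_scale: float = 0.10      # amplitude of within-archetype trajectory wiggles
    level_sd: float = 0.03         # per-resident constant latent level offset
    attr_noise: float = 0.08       # per-exam, per-attribute severity noise
    attr_bias_sd: float = 0.10     # per-resident biomarker setpoint offsets
    label_steepness: float = 8.0
    label_center: float = 0.55
    seed: int = 0

    def validate(self) -> None:
        if self.n_residents < 2:
            raise ValueError("a cohort needs at least two residents")
        if not 0.0 < self.attendance_prob <= 1.0:
            raise ValueError("attendance_prob must lie in (0, 1]")
        if self.n_archetypes < 2:
            raise ValueError("need at least two trajectory archetypes")
        if self.grid_length < 4:
            raise ValueError("grid_length must be at least 4")


#: archetype latent shapes: (relative knot positions in [0,1], severities)
_BASE_SHAPES: tuple[tuple[tuple[float, ...], tuple[float, ...]], ...] = (
    ((0.0, 0.3, 0.7, 1.0), (0.20, 0.35, 0.62, 0.80)),    # steadily worsening
    ((0.0, 0.35, 0.65, 1.0), (0.50, 0.55, 0.47, 0.52)),  # stable mid-risk
    ((0.0, 0.3, 0.75, 1.0), (0.80, 0.65, 0.40, 0.22)),   # improving
)

#: severity quantization of the time-varying attributes: codes in ascending
#: risk order and the severity cut points between consecutive codes
_TIME_VARYING: dict[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    "exercise_frequency": ((2, 3, 4, 1), (0.30, 0.60, 0.88)),
    "central_obesity": ((0, 1), (0.55,)),
    "bmi": ((1, 2, 3), (0.35, 0.65)),
    "diabetes": ((0, 1), (0.70,)),
    "heart_rate": ((1, 2), (0.75,)),
    "blood_urea": ((1, 2), (0.60,)),
    "total_cholesterol": ((2, 1), (0.82,)),
    "triglyceride": ((1, 2, 3), (0.40, 0.80)),
    "ldl_cholesterol": ((0, 1), (0.65,)),
    "hdl_cholesterol": ((0, 1), (0.45,)),
}

#: representative raw numeric value for each code of the range attributes
_NUMERIC_REPRESENTATIVE: dict[str, dict[int, float]] = {
    "age": {1: 72.0, 2: 50.0, 3: 29.0},
    "bmi": {1: 21.5, 2: 26.0, 3: 30.5, 4: 17.5},
    "heart_rate": {1: 75.0, 2: 108.0, 3: 52.0},
    "blood_urea": {1: 5.2, 2: 8.1, 3: 2.6},
    "total_cholesterol": {1: 6.0, 2: 4.4, 3: 2.6},
    "triglyceride": {1: 1.2, 2: 2.8, 3: 6.2},
    "ldl_cholesterol": {0: 3.1, 1: 4.6},
    "hdl_cholesterol": {0: 1.5, 1: 1.0},
}

#: population frequencies of the static demographic attributes
_DEMOGRAPHICS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "gender": (("Female", "Male"), (0.5, 0.5)),
    "dietary_habit": (("Meat diet", "Vegetarian diet", "Equilibrium"),
                      (0.3, 0.2, 0.5)),
    "smoking": (("Yes", "Never", "Quitting"), (0.25, 0.6, 0.15)),
    "drinking": (("Everyday", "Frequently", "Never", "Occasionally"),
                 (0.1, 0.2, 0.45, 0.25)),
    "heart_rhythm": (("Normal", "Arrhythmia"), (0.95, 0.05)),
}


def _raw_for_code(scheme: EncodingScheme, name: str, code: int):
    """A raw value that the scheme encodes to the requested code."""
    attr = scheme[name]
    if isinstance(attr, CategoricalAttribute):
        for raw, c in attr.mapping.items():
            if c == code:
                return raw
        raise ValueError(f"{name}: no category with code {code}")
    assert isinstance(attr, RangeAttribute)
    return _NUMERIC_REPRESENTATIVE[name][code]


@dataclass
class TopK:
    """Ranked ground-truth neighbour list; ``complete`` is False when the
    archetype holds fewer than the requested k mates."""

    ids: list[str]
    complete: bool = True


@dataclass
class SyntheticCohort:
    """A generated cohort together with its planted ground truth."""

    cohort: Cohort
    archetypes: dict[str, int]
    latent: dict[str, np.ndarray]          # latent severity on the full grid
    tgrid: np.ndarray
    config: SimConfig
    _truth_cache: dict = field(default_factory=dict, repr=False)

    def ids(self) -> list[str]:
        return self.cohort.ids()

    def observed_support(self, resident_id: str) -> tuple[float, float]:
        exams = self.cohort.exams(resident_id)
        return float(exams[0].exam_index), float(exams[-1].exam_index)

    def latent_on(self, resident_id: str, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.tgrid, self.latent[resident_id])

    def ground_truth_topk(self, target_id: str, k: int = 10) -> TopK:
        """Same-archetype residents ranked by latent L2 distance over the
        target's observed exam window."""
        if target_id not in self.cohort:
            raise KeyError(f"unknown resident {target_id!r}")
        if k < 1:
            raise ValueError("k must be at least 1")
        key = (target_id, k)
        if key in self._truth_cache:
            return self._truth_cache[key]
        lo, hi = self.observed_support(target_id)
        dense = np.linspace(lo, hi, 64) if hi > lo else np.array([lo])
        mine = self.latent_on(target_id, dense)
        arch = self.archetypes[target_id]
        scored = []
        for rid in self.cohort.ids():
            if rid == target_id or self.archetypes[rid] != arch:
                continue
            d = self.latent_on(rid, dense) - mine
            scored.append((float(np.sqrt(np.trapezoid(d * d, dense))) if hi > lo
                           else float(np.abs(d[0])), rid))
        scored.sort()
        result = TopK(ids=[rid for _, rid in scored[:k]],
                      complete=len(scored) >= k)
        self._truth_cache[key] = result
        return result

    def write_ground_truth(self, path: str | Path, k: int = 10) -> None:
        payload = {
            rid: self.ground_truth_topk(rid, k).ids for rid in self.cohort.ids()
        }
        Path(path).write_text(json.dumps(
            {"k": k, "archetypes": self.archetypes, "neighbors": payload},
            indent=2))


def ground_truth_topk(cohort: SyntheticCohort, target_id: str, k: int = 10) -> TopK:
    """Functional alias for :meth:`SyntheticCohort.ground_truth_topk`."""
    return cohort.ground_truth_topk(target_id, k)


def _archetype_shapes(config: SimConfig, rng: np.random.Generator) -> list:
    shapes = list(_BASE_SHAPES[:config.n_archetypes])
    while len(shapes) < config.n_archetypes:
        pos = np.sort(np.concatenate([[0.0, 1.0], rng.uniform(0.1, 0.9, 2)]))
        vals = rng.uniform(0.3, 0.72, len(pos))
        shapes.append((tuple(pos), tuple(vals)))
    return shapes


def simulate_cohort(config: SimConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a synthetic cohort; same config (incl. seed) -> same cohort."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a SimConfig or keyword overrides, not both")
    config.validate()
    rng = np.random.default_rng(config.seed)
    scheme = default_scheme()
    tgrid = np.arange(1, config.grid_length + 1, dtype=float)
    span = config.grid_length - 1
    shapes = _archetype_shapes(config, rng)
    wiggle_knots = np.linspace(1, config.grid_length, 6)

    cohort = Cohort(scheme=scheme, grid_length=config.grid_length)
    archetypes: dict[str, int] = {}
    latent: dict[str, np.ndarray] = {}
    tv_names = list(_TIME_VARYING)

    for r in range(config.n_residents):
        rid = f"R{r:05d}"
        arch = int(rng.integers(config.n_archetypes))
        pos, vals = shapes[arch]
        base = np.interp(tgrid, 1.0 + span * np.asarray(pos), np.asarray(vals))
        offset = rng.normal(0.0, config.level_sd)
        wiggle = np.interp(tgrid, wiggle_knots,
                           rng.normal(0.0, config.noise_scale, len(wiggle_knots)))
        traj = np.clip(base + offset + wiggle, 0.02, 0.98)

        # irregular attendance; guarantee at least two attended exams
        u = rng.random(config.grid_length)
        keep = u < config.attendance_prob
        if keep.sum() < 2:
            keep[np.argsort(u)[:2]] = True

        # static demographics, independent of the trajectory
        raw_static: dict[str, object] = {}
        for name, (cats, probs) in _DEMOGRAPHICS.items():
            raw_static[name] = cats[int(rng.choice(len(cats), p=probs))]
        raw_static["age"] = float(rng.uniform(25.0, 80.0))
        # demographic baseline risk: shifts the label odds (so the forest
        # learns to weight these attributes) without moving the trajectory
        demo_shift = (
            0.20 * (raw_static["age"] - 25.0) / 55.0
            + 0.06 * (raw_static["smoking"] == "Yes")
            + 0.05 * (raw_static["drinking"] in ("Everyday", "Frequently"))
            - 0.13
        )
        # personal biomarker setpoints: persistent severity offsets per
        # attribute (someone's BMI or lipids run high independent of their
        # current trajectory)
        setpoint = rng.normal(0.0, config.attr_bias_sd, len(tv_names))

        for t_idx in np.nonzero(keep)[0]:
            t = tgrid[t_idx]
            raw = dict(raw_static)
            sev = np.clip(
                traj[t_idx] + setpoint
                + rng.normal(0.0, config.attr_noise, len(tv_names)),
                0.0, 1.0,
            )
            for s, name in zip(sev, tv_names):
                codes, edges = _TIME_VARYING[name]
                code = codes[int(np.searchsorted(edges, s))]
                raw[name] = _raw_for_code(scheme, name, code)
            p = float(expit(config.label_steepness
                            * (traj[t_idx] + demo_shift - config.label_center)))
            label = int(rng.random() < p)
            cohort.add(ExamRecord.from_raw(rid, int(t), raw, label, scheme))

        archetypes[rid] = arch
        latent[rid] = traj

    return SyntheticCohort(cohort=cohort, archetypes=archetypes, latent=latent,
                           tgrid=tgrid, config=config)


def simulate_single_signal_cohort(attribute: str = "bmi", n_residents: int = 200,
                                  exams_per_resident: int = 10,
                                  flip_prob: float = 0.05,
                                  seed: int = 0) -> Cohort:
    """Cohort in which exactly one attribute determines the label.

    All attribute codes are drawn uniformly and independently; the label is
    1 when the chosen attribute's code falls in the upper half of its code
    range, with a small label-flip probability.  Used to check that the
    weighting forest concentrates its importance on the informative
    attribute.
    """
    rng = np.random.default_rng(seed)
    scheme = default_scheme()
    if attribute not in scheme.names:
        raise ValueError(f"unknown attribute {attribute!r}")
    cohort = Cohort(scheme=scheme)
    for r in range(n_residents):
        rid = f"P{r:05d}"
        for t in range(1, exams_per_resident + 1):
            raw: dict[str, object] = {}
            for attr in scheme.attributes:
                code = int(rng.choice(attr.codes))
                raw[attr.name] = _raw_for_code(scheme, attr.name, code)
            codes = scheme[attribute].codes
            signal = scheme[attribute].encode(raw[attribute]) >= np.median(codes)
            label = int(signal) ^ int(rng.random() < flip_prob)
            cohort.add(ExamRecord.from_raw(rid, t, raw, label, scheme))
    return cohort
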