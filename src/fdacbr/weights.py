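"""Attribute weighting by random-forest mean decrease in Gini impurity.

Every examination contributes one training row (features: the encoded
attribute codes; label: concurrent hypertension status).  A bagged forest
of depth-limited CART trees is fitted, the mean impurity decrease D_i
attributable to each attribute is averaged over trees, and the weights are
the normalized decreases w_i = D_i / sum_j D_j.

The forest itself is scikit-learn's RandomForestClassifier; by default every
feature is considered at each split (pure bagging), which makes the learned
weights equivariant under permutation of the attribute columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .encoding import Cohort

__all__ = [
    "WeightVector",
    "gini_impurity",
    "fit_forest_weights",
    "load_published_weights",
    "PUBLISHED_WEIGHTS",
]


def gini_impurity(class_probs) -> float:
    """Gini impurity 1 - sum_j p_j^2 of a class-probability vector.

    Zero for a pure node; maximal, at 1 - 1/k, for the uniform distribution
    over k classes.
    """
    p = np.asarray(class_probs, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("class probabilities must form a non-empty 1-D vector")
    if np.any(p < 0):
        raise ValueError("class probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"class probabilities must sum to 1, got {p.sum()}")
    return float(1.0 - np.sum(p**2))


@dataclass
class WeightVector:
    """Per-attribute importance weights aligned to an encoding scheme order."""

    names: tuple[str, ...]
    values: np.ndarray
    gini_decrease: np.ndarray | None = None
    config: dict = field(default_factory=dict)
    normalized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("one weight per attribute name required")
        if np.any(self.values < 0):
            raise ValueError("weights must be nonnegative")
        if self.normalized and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"normalized weights must sum to 1, got {self.values.sum():.12f}"
            )

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def renormalized(self) -> "WeightVector":
        """A copy rescaled to sum exactly to one."""
        return WeightVector(
            names=self.names, values=self.values / self.values.sum(),
            gini_decrease=self.gini_decrease,
            config={**self.config, "renormalized": True}, normalized=True,
        )

    def reordered(self, names: tuple[str, ...]) -> "WeightVector":
        """A copy aligned to a different attribute order (same name set)."""
        if set(names) != set(self.names):
            raise ValueError("attribute name sets differ")
        idx = [self.names.index(n) for n in names]
        return WeightVector(
            names=tuple(names), values=self.values[idx],
            gini_decrease=None if self.gini_decrease is None
            else self.gini_decrease[idx],
            config=dict(self.config), normalized=self.normalized,
        )

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": {n: float(v) for n, v in zip(self.names, self.values)},
            "order": list(self.names),
            "config": self.config,
            "normalized": self.normalized,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightVector":
        d = json.loads(Path(path).read_text())
        names = tuple(d["order"])
        return cls(
            names=names,
            values=np.array([d["weights"][n] for n in names], dtype=float),
            config=d.get("config", {}),
            normalized=bool(d.get("normalized", True)),
        )


def fit_forest_weights(cohort: Cohort, depth: int = 5, n_trees: int = 500,
                       seed: int = 0, max_features=None) -> WeightVector:
    """Fit the weighting forest on a cohort and return normalized weights.

    One row per examination.  D_i is the mean (over trees) total impurity
    decrease from splits on attribute i, each split weighted by the fraction
    of bootstrap samples reaching its node; w_i = D_i / sum_j D_j.
    """
    X, y = cohort.feature_matrix()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            "cannot fit attribute weights: cohort labels contain a single class"
        )
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_depth=depth, bootstrap=True,
        max_features=max_features, random_state=int(seed), n_jobs=1,
    )
    forest.fit(X, y)
    per_tree = np.array([
        est.tree_.compute_feature_importances(normalize=False)
        for est in forest.estimators_
    ])
    D = per_tree.mean(axis=0)
    total = D.sum()
    if total <= 0:  # pragma: no cover - needs a constant-feature cohort
        raise ValueError("forest produced no informative splits")
    return WeightVector(
        names=cohort.scheme.names,
        values=D / total,
        gini_decrease=D,
        config={"depth": depth, "n_trees": n_trees, "seed": int(seed),
                "max_features": max_features},
    )


#: Published per-attribute weights of the original hypertension study
#: (community EHR cohort), in the table's own order.  They are reference
#: values only: the printed 16 rows sum to 1.083, and the source table
#: elides further attributes, so the fixture is not a valid probability
#: vector as printed.
PUBLISHED_WEIGHTS: tuple[tuple[str, float], ...] = (
    ("age", 0.301),
    ("diabetes", 0.152),
    ("exercise_frequency", 0.112),
    ("bmi", 0.103),
    ("total_cholesterol", 0.073),
    ("smoking", 0.051),
    ("drinking", 0.049),
    ("central_obesity", 0.041),
    ("triglyceride", 0.032),
    ("blood_urea", 0.031),
    ("hdl_cholesterol", 0.028),
    ("heart_rhythm", 0.027),
    ("gender", 0.024),
    ("heart_rate", 0.023),
    ("ldl_cholesterol", 0.019),
    ("dietary_habit", 0.017),
)


def load_published_weights(renormalize: bool = False) -> WeightVector:
    """The published reference weight table as a WeightVector fixture.

    With ``renormalize=False`` the values are exactly as printed (summing to
    1.083, recorded in ``config['printed_sum']``); with ``renormalize=True``
    they are rescaled to sum to one.
    """
    names = tuple(n for n, _ in PUBLISHED_WEIGHTS)
    values = np.array([v for _, v in PUBLISHED_WEIGHTS])
    wv = WeightVector(
        names=names, values=values,
        config={"source": "published reference table",
                "printed_sum": float(values.sum()),
                "elided_rows": True},
        normalized=False,
    )
    return wv.renormalized() if renormalize else wv
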