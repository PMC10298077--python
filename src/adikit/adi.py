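"""The composite applicability-domain index (ADI).

A prediction for a query compound is qualified by interrogating the wrapped
model's knowledge base along three axes — chemistry (similarity to training
compounds, fragment rarity, descriptor ranges), endpoint (how well the
model predicts the query's nearest training neighbors, and how well those
neighbors' experimental values agree with the query's prediction), and
algorithm (sensitivity of the prediction to small descriptor
perturbations).  Each raw component index is mapped through a model-specific
piecewise-linear threshold function onto [0, 1], and the ADI is the product
of the applicable subscores, further multiplied by a penalty for each failed
boolean check (out-of-range descriptors, outlier-associated fragments).

The ADI is then bucketed into three reliability categories: high (> 0.85,
three stars), moderate (0.75–0.85 inclusive, two stars), low (< 0.75, one
star).  Boundaries and every component threshold are per-model
configuration, not constants of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import yaml

from .chemspace import Molecule
from .knowledge_base import (
    NOT_APPLICABLE,
    KnowledgeBase,
    SimilarNeighbor,
    acf_index,
    range_check,
    rank_all,
)

REGRESSION = "regression"
CLASSIFICATION = "classification"

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"

CATEGORY_STARS = {"low": 1, "moderate": 2, "high": 3}

# alert-concordance outcomes
ALERT_CONCORDANT = "concordant"
ALERT_TARGET_ONLY = "target_only"
ALERT_NEIGHBOR_ONLY = "neighbor_only"
ALERT_NONE = "none"


@dataclass
class ModelAdapter:
    """Uniform wrapper around any predictor whose AD is being assessed.

    ``predict`` must be deterministic for a fixed structure.  The optional
    capabilities switch individual ADI components on: ``descriptors``
    enables the range check, ``predict_from_descriptors`` additionally
    enables the perturbation-sensitivity check, ``alerts`` enables the
    structural-alert cross-check, and ``outlier_fragments`` enables the
    outlier-fragment flag.  Absent capabilities leave their component
    not-applicable (excluded from aggregation), never zero.
    """

    task_type: str
    predict: Callable[[Molecule], object]
    descriptors: Optional[Callable[[Molecule], dict]] = None
    predict_from_descriptors: Optional[Callable[[dict], float]] = None
    alerts: Optional[Callable[[Molecule], set]] = None
    outlier_fragments: Optional[set] = None
    supports_range_check: bool = True
    name: str = "model"


@dataclass(frozen=True)
class ComponentThreshold:
    orientation: str  # HIGHER_BETTER | LOWER_BETTER
    t_good: float
    t_bad: float


#: shipped defaults for regression models on log-unit endpoints
DEFAULT_REGRESSION_THRESHOLDS = {
    "similarity": ComponentThreshold(HIGHER_BETTER, 0.9, 0.6),
    "accuracy": ComponentThreshold(LOWER_BETTER, 0.5, 1.5),
    "concordance": ComponentThreshold(LOWER_BETTER, 0.5, 1.5),
    "max_error": ComponentThreshold(LOWER_BETTER, 0.75, 2.0),
    "acf": ComponentThreshold(HIGHER_BETTER, 1.0, 0.0),
    "sensitivity": ComponentThreshold(LOWER_BETTER, 0.1, 1.0),
}

#: shipped defaults for classifiers (accuracy/concordance are fractions of
#: top-k neighbors; max error is the similarity of the best-ranked
#: misclassified neighbor)
DEFAULT_CLASSIFICATION_THRESHOLDS = {
    "similarity": ComponentThreshold(HIGHER_BETTER, 0.9, 0.6),
    "accuracy": ComponentThreshold(HIGHER_BETTER, 1.0, 0.0),
    "concordance": ComponentThreshold(HIGHER_BETTER, 1.0, 0.0),
    "max_error": ComponentThreshold(LOWER_BETTER, 0.0, 1.0),
    "acf": ComponentThreshold(HIGHER_BETTER, 1.0, 0.0),
    "sensitivity": ComponentThreshold(LOWER_BETTER, 0.1, 1.0),
}


@dataclass
class ADIConfig:
    """Per-model ADI configuration.

    ``k`` is the number of most-similar compounds the component indices are
    measured on (two by default, three for some endpoints); ``n_display``
    is how many neighbors are shown to the user (six).  ``bool_multiplier``
    is the penalty applied once per failed boolean check; the default 0.6
    caps the ADI below the low/moderate boundary on a single failure.
    """

    task_type: str = REGRESSION
    k: int = 2
    n_display: int = 6
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_REGRESSION_THRESHOLDS))
    bool_multiplier: float = 0.6
    low_high: float = 0.75
    moderate_high: float = 0.85
    perturbation_delta: float = 0.01
    acf_f_known: int = 3
    acf_w_rare: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.low_high < self.moderate_high <= 1.0):
            raise ValueError("need 0 <= low_high < moderate_high <= 1")
        if self.k > self.n_display:
            raise ValueError("k must not exceed n_display")
        if not (0.0 < self.bool_multiplier <= 1.0):
            raise ValueError("bool_multiplier must be in (0, 1]")

    @classmethod
    def for_task(cls, task_type: str, **overrides) -> "ADIConfig":
        thresholds = dict(
            DEFAULT_CLASSIFICATION_THRESHOLDS
            if task_type == CLASSIFICATION
            else DEFAULT_REGRESSION_THRESHOLDS
        )
        return cls(task_type=task_type, thresholds=thresholds, **overrides)

    @classmethod
    def from_dict(cls, data: dict) -> "ADIConfig":
        data = dict(data)
        task = data.get("task_type", REGRESSION)
        base = cls.for_task(task)
        thresholds = dict(base.thresholds)
        for name, spec in data.pop("thresholds", {}).items():
            if name not in thresholds:
                raise KeyError(f"unknown ADI component in config: {name!r}")
            thresholds[name] = ComponentThreshold(
                spec.get("orientation", thresholds[name].orientation),
                float(spec["t_good"]),
                float(spec["t_bad"]),
            )
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown ADI config key(s): {sorted(unknown)}")
        return cls(thresholds=thresholds, **{**data, "task_type": task})

    @classmethod
    def from_file(cls, path) -> "ADIConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_thresholds(self, **named: ComponentThreshold) -> "ADIConfig":
        merged = {**self.thresholds, **named}
        return replace(self, thresholds=merged)


@dataclass
class ADIComponents:
    """Raw (unscored) component values for one query compound."""

    similarity_index: float
    accuracy_index: Optional[float]
    concordance_index: Optional[float]
    max_error_index: Optional[float]
    acf_index: float
    range_check: object  # True | False | NOT_APPLICABLE
    range_violations: list = field(default_factory=list)
    sensitivity_index: Optional[object] = NOT_APPLICABLE
    outlier_fragment_hit: object = NOT_APPLICABLE
    alert_concordance: object = NOT_APPLICABLE


@dataclass
class ADIResult:
    adi: float
    category: str
    stars: int
    components: ADIComponents
    subscores: dict[str, float]
    neighbors: list[SimilarNeighbor]
    warnings: list[str]
    prediction: object = None
    target_id: str = ""
    target_smiles: str = ""


def _usable(neighbors: list[SimilarNeighbor], k: int) -> list[SimilarNeighbor]:
    """Top-k neighbors with experimental values; lower-ranked neighbors are
    promoted past any with a missing value."""
    usable = [n for n in neighbors if n.record.experimental is not None]
    return usable[:k]


def similarity_index(neighbors: list[SimilarNeighbor], k: int) -> float:
    """Mean similarity of the k most similar compounds."""
    if not neighbors:
        raise ValueError("no neighbors")
    top = neighbors[:k]
    return sum(n.similarity for n in top) / len(top)


def accuracy_index(neighbors: list[SimilarNeighbor], k: int, task: str) -> Optional[float]:
    """How well the model predicts the query's nearest training compounds.

    Regression: mean absolute error |predicted - experimental| over the
    top-k neighbors, in the endpoint's (log) units — lower is better.
    Classification: fraction of top-k neighbors predicted correctly —
    higher is better.
    """
    top = _usable(neighbors, k)
    if not top:
        return None
    if task == REGRESSION:
        return sum(abs(float(n.record.predicted) - float(n.record.experimental)) for n in top) / len(top)
    return sum(1 for n in top if n.record.predicted == n.record.experimental) / len(top)


def concordance_index(
    neighbors: list[SimilarNeighbor], k: int, target_prediction, task: str
) -> Optional[float]:
    """Agreement between the query's predicted value and the experimental
    values of its nearest training compounds (the read-across check).

    Regression: mean |experimental_i - prediction| (lower better).
    Classification: fraction of top-k whose experimental label equals the
    predicted label (higher better).
    """
    top = _usable(neighbors, k)
    if not top:
        return None
    if task == REGRESSION:
        return sum(abs(float(n.record.experimental) - float(target_prediction)) for n in top) / len(top)
    return sum(1 for n in top if n.record.experimental == target_prediction) / len(top)


def max_error_index(neighbors: list[SimilarNeighbor], k: int, task: str) -> Optional[float]:
    """Whether any nearby training compound is predicted very badly.

    Regression: max |predicted - experimental| over the top-k (lower
    better).  Classification: the similarity of the best-ranked
    misclassified neighbor, 0.0 when all top-k are classified correctly —
    a close misclassified neighbor is a strong warning.
    """
    top = _usable(neighbors, k)
    if not top:
        return None
    if task == REGRESSION:
        return max(abs(float(n.record.predicted) - float(n.record.experimental)) for n in top)
    missed = [n.similarity for n in top if n.record.predicted != n.record.experimental]
    return max(missed) if missed else 0.0


def sensitivity_check(model: ModelAdapter, target: Molecule, delta: float = 0.01):
    """Largest prediction shift under a small descriptor perturbation.

    Each descriptor d is perturbed to d(1 ± delta) (± delta absolute when
    d = 0) and the model re-predicts from the perturbed descriptor vector;
    the index is the maximum |Δprediction| over descriptors and signs.  A
    model whose prediction jumps under a 1% descriptor nudge is operating
    near a decision boundary and its prediction is fragile.  Returns
    NOT_APPLICABLE when the adapter cannot predict from descriptors.
    """
    if model.descriptors is None or model.predict_from_descriptors is None:
        return NOT_APPLICABLE
    desc = dict(model.descriptors(target))
    if not desc:
        return NOT_APPLICABLE
    try:
        baseline = float(model.predict_from_descriptors(desc))
        worst = 0.0
        for name, value in desc.items():
            step = abs(value) * delta if value != 0 else delta
            for sign in (+1.0, -1.0):
                perturbed = dict(desc)
                perturbed[name] = value + sign * step
                shifted = float(model.predict_from_descriptors(perturbed))
                worst = max(worst, abs(shifted - baseline))
    except Exception:
        return NOT_APPLICABLE
    return worst


def alert_and_outlier_checks(
    model: ModelAdapter, target: Molecule, neighbors: list[SimilarNeighbor]
) -> tuple[object, object]:
    """Structural-alert cross-check and outlier-fragment flag.

    The alert check classifies the overlap between the target's alerts and
    those of its nearest neighbors; a neighbor-only alert suggests the user
    may disregard that neighbor (its adverse-effect fragment is absent from
    the target).  The outlier flag fires when any target ACF belongs to the
    model's declared set of fragments associated with poorly predicted
    chemical families.  Either check is NOT_APPLICABLE when the adapter
    lacks the capability.
    """
    if model.alerts is None:
        alert_outcome = NOT_APPLICABLE
    else:
        target_alerts = set(model.alerts(target))
        neighbor_alerts: set = set()
        for n in neighbors:
            neighbor_alerts |= set(model.alerts(n.record.molecule))
        if not target_alerts and not neighbor_alerts:
            alert_outcome = ALERT_NONE
        elif target_alerts & neighbor_alerts:
            alert_outcome = ALERT_CONCORDANT
        elif target_alerts:
            # covers both "target only" and disjoint alerts on both sides;
            # the target's own alert is the primary signal either way
            alert_outcome = ALERT_TARGET_ONLY
        else:
            alert_outcome = ALERT_NEIGHBOR_ONLY
    if model.outlier_fragments is None:
        outlier_hit = NOT_APPLICABLE
    else:
        outlier_hit = bool(set(target.acfs) & set(model.outlier_fragments))
    return alert_outcome, outlier_hit


def score_component(raw: float, threshold: ComponentThreshold) -> float:
    """Map a raw component value onto [0, 1] piecewise-linearly.

    1 at-or-beyond t_good, 0 at-or-beyond t_bad, linear in between;
    monotone in the raw value for either orientation.
    """
    t_good, t_bad = threshold.t_good, threshold.t_bad
    if t_good == t_bad:
        raise ValueError("t_good and t_bad must differ")
    if threshold.orientation == HIGHER_BETTER:
        if raw >= t_good:
            return 1.0
        if raw <= t_bad:
            return 0.0
    elif threshold.orientation == LOWER_BETTER:
        if raw <= t_good:
            return 1.0
        if raw >= t_bad:
            return 0.0
    else:
        raise ValueError(f"unknown orientation {threshold.orientation!r}")
    return (raw - t_bad) / (t_good - t_bad)


def categorize(adi: float, low_high: float = 0.75, moderate_high: float = 0.85) -> tuple[str, int]:
    """Bucket an ADI value: > moderate_high is high (3 stars); the closed
    interval [low_high, moderate_high] is moderate (2 stars); below
    low_high is low (1 star)."""
    if adi > moderate_high:
        cat = "high"
    elif adi >= low_high:
        cat = "moderate"
    else:
        cat = "low"
    return cat, CATEGORY_STARS[cat]


_COMPONENT_LABELS = {
    "similarity": "similarity index",
    "accuracy": "accuracy of neighbor predictions",
    "concordance": "concordance with neighbor experimental values",
    "max_error": "max neighbor prediction error",
    "acf": "ACF index (rare/unknown fragments)",
    "sensitivity": "descriptor-perturbation sensitivity",
}


def aggregate(components: ADIComponents, config: ADIConfig) -> ADIResult:
    """Combine scored components into the overall ADI and categorize it.

    The ADI is the product of the applicable components' [0, 1] subscores,
    multiplied once by ``bool_multiplier`` for each failed boolean check
    (range check false, outlier fragment present), clamped to [0, 1].
    Not-applicable components are excluded rather than treated as perfect
    or failed.  A warning is emitted for every subscore below 1 and every
    failed boolean.
    """
    raw = {
        "similarity": components.similarity_index,
        "accuracy": components.accuracy_index,
        "concordance": components.concordance_index,
        "max_error": components.max_error_index,
        "acf": components.acf_index,
        "sensitivity": components.sensitivity_index,
    }
    subscores: dict[str, float] = {}
    warnings: list[str] = []
    for name, value in raw.items():
        if value is None or value == NOT_APPLICABLE:
            continue
        subscores[name] = score_component(float(value), config.thresholds[name])
        if subscores[name] < 1.0:
            warnings.append(
                f"{_COMPONENT_LABELS[name]} below ideal "
                f"(raw {float(value):.3f}, subscore {subscores[name]:.3f})"
            )
    if not subscores:
        raise ValueError("no applicable ADI components; cannot assess applicability domain")
    adi = 1.0
    for s in subscores.values():
        adi *= s
    if components.range_check is False:
        adi *= config.bool_multiplier
        names = ", ".join(components.range_violations) or "descriptors"
        warnings.append(f"descriptor range check failed: {names} outside training range")
    if components.outlier_fragment_hit is True:
        adi *= config.bool_multiplier
        warnings.append("fragment associated with endpoint outliers present in target")
    if components.alert_concordance == ALERT_NEIGHBOR_ONLY:
        warnings.append(
            "structural alert present in similar compound(s) but absent from target; "
            "those neighbors may be disregarded"
        )
    elif components.alert_concordance == ALERT_TARGET_ONLY:
        warnings.append("structural alert present in target but not in its similar compounds")
    adi = min(max(adi, 0.0), 1.0)
    category, stars = categorize(adi, config.low_high, config.moderate_high)
    return ADIResult(
        adi=adi,
        category=category,
        stars=stars,
        components=components,
        subscores=subscores,
        neighbors=[],
        warnings=warnings,
    )


def assess_compound(
    kb: KnowledgeBase,
    model: ModelAdapter,
    target: Molecule,
    config: Optional[ADIConfig] = None,
    exclude_self: bool = False,
) -> ADIResult:
    """Full per-compound AD assessment: predict, rank neighbors, compute
    every applicable component, aggregate, and categorize."""
    if config is None:
        config = ADIConfig.for_task(model.task_type)
    ranking = rank_all(kb, target, exclude_self=exclude_self)
    prediction = model.predict(target)
    few = len(ranking) < config.k or len(_usable(ranking, config.k)) < config.k
    desc = model.descriptors(target) if model.descriptors is not None else None
    rc, violations = range_check(kb, target, desc, supported=model.supports_range_check)
    alert_outcome, outlier_hit = alert_and_outlier_checks(model, target, ranking[: config.k])
    components = ADIComponents(
        similarity_index=similarity_index(ranking, config.k),
        accuracy_index=accuracy_index(ranking, config.k, config.task_type),
        concordance_index=concordance_index(ranking, config.k, prediction, config.task_type),
        max_error_index=max_error_index(ranking, config.k, config.task_type),
        acf_index=acf_index(kb, target, config.acf_f_known, config.acf_w_rare),
        range_check=rc,
        range_violations=violations,
        sensitivity_index=sensitivity_check(model, target, config.perturbation_delta),
        outlier_fragment_hit=outlier_hit,
        alert_concordance=alert_outcome,
    )
    result = aggregate(components, config)
    result.neighbors = ranking[: config.n_display]
    result.prediction = prediction
    result.target_id = target.id
    result.target_smiles = target.smiles_canonical
    if few:
        result.warnings.insert(0, f"fewer than k={config.k} usable neighbors available")
    return result
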