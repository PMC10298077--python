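"""AD-stratified performance assessment of a wrapped predictor.

Given a training-only knowledge base and a held-out test set, every test
compound receives an ADI and is placed in one of three strata — high
("in AD"), moderate ("possibly out of AD"), low ("out of AD") — and the
model's performance (accuracy for classifiers, coefficient of
determination for regression, plus auxiliaries) is reported per stratum.
A well-behaved AD tool shows its best statistics in the high stratum and
its worst in the low one.

Metrics are hand-computed from their closed forms rather than delegated so
that degenerate strata (constant labels, tiny n) can be reported as
not-available instead of silently returning 0; the closed forms are
cross-checked against scikit-learn in the test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .adi import ADIConfig, ADIResult, ModelAdapter, REGRESSION, assess_compound
from .chemspace import ParseError, parse_molecule
from .knowledge_base import KnowledgeBase

STRATA = ("high", "moderate", "low")
STRATUM_LABELS = {"high": "in AD", "moderate": "possibly out of AD", "low": "out of AD"}

#: strata smaller than these report not-available instead of a metric
MIN_N_CLASSIFICATION = 2
MIN_N_REGRESSION = 3


@dataclass
class PredictionOutcome:
    compound_id: str
    experimental: object
    predicted: object
    adi_result: ADIResult


@dataclass
class StratifiedPerformance:
    task_type: str
    strata: dict[str, dict]  # stratum -> {"n": int, "metrics": {...}}
    overall: dict
    outcomes: list[PredictionOutcome] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)  # test ids found in the KB

    @property
    def n_total(self) -> int:
        return sum(s["n"] for s in self.strata.values())

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (stratum, metric)."""
        rows = []
        for name in (*STRATA, "overall"):
            block = self.overall if name == "overall" else self.strata[name]
            rows.append({"stratum": name, "n": block["n"], "metric": "n", "value": block["n"]})
            for metric, value in block["metrics"].items():
                rows.append(
                    {"stratum": name, "n": block["n"], "metric": metric,
                     "value": value if value is not None else float("nan")}
                )
        return pd.DataFrame(rows, columns=["stratum", "n", "metric", "value"])

    def to_json(self) -> str:
        doc = {
            "task_type": self.task_type,
            "strata": self.strata,
            "overall": self.overall,
            "excluded": self.excluded,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    def plot(self, metric: str, path) -> None:
        """Bar chart of one metric across strata (SVG/PNG by extension)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        values = [self.strata[s]["metrics"].get(metric) for s in STRATA]
        labels = [f"{STRATUM_LABELS[s]}\n(n={self.strata[s]['n']})" for s in STRATA]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.bar(labels, [v if v is not None else 0.0 for v in values], color="#4878a8")
        ax.set_ylabel(metric)
        ax.set_title(f"{metric} by applicability-domain stratum")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def classification_metrics(pairs: Sequence[tuple[object, object]]) -> dict:
    """Accuracy, and for binary tasks sensitivity/specificity/MCC.

    MCC is not-available (None) when any marginal of the confusion table is
    zero.  For binary tasks the positive class is the larger label under
    sorted order (e.g. 1 vs 0, "active" vs "inactive" alphabetically
    reversed), which only affects which rate is called sensitivity.
    """
    if not pairs:
        raise ValueError("no prediction pairs")
    n = len(pairs)
    correct = sum(1 for exp, pred in pairs if exp == pred)
    metrics: dict = {"accuracy": correct / n}
    labels = sorted({exp for exp, _ in pairs} | {pred for _, pred in pairs})
    if len(labels) == 1:
        # degenerate: a single observed label; binary rates are undefined
        metrics.update({"sensitivity": None, "specificity": None, "mcc": None})
    elif len(labels) == 2:
        neg, pos = labels
        tp = sum(1 for e, p in pairs if e == pos and p == pos)
        tn = sum(1 for e, p in pairs if e == neg and p == neg)
        fp = sum(1 for e, p in pairs if e == neg and p == pos)
        fn = sum(1 for e, p in pairs if e == pos and p == neg)
        metrics["sensitivity"] = tp / (tp + fn) if (tp + fn) else None
        metrics["specificity"] = tn / (tn + fp) if (tn + fp) else None
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        metrics["mcc"] = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None
    return metrics


def regression_metrics(pairs: Sequence[tuple[float, float]]) -> dict:
    """R² (coefficient of determination, primary), RMSE, MAE, and squared
    Pearson correlation (secondary).

    R² = 1 - SSres/SStot with the experimental values as reference; it is
    not-available when the experimental values are constant (SStot = 0),
    and the whole set of metrics is not-available below n = 2.
    """
    n = len(pairs)
    if n < 2:
        return {"r2": None, "rmse": None, "mae": None, "pearson_r2": None}
    exp = [float(e) for e, _ in pairs]
    pred = [float(p) for _, p in pairs]
    mean_exp = sum(exp) / n
    ss_res = sum((e - p) ** 2 for e, p in zip(exp, pred))
    ss_tot = sum((e - mean_exp) ** 2 for e in exp)
    rmse = math.sqrt(ss_res / n)
    mae = sum(abs(e - p) for e, p in zip(exp, pred)) / n
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    mean_pred = sum(pred) / n
    sxx = sum((e - mean_exp) ** 2 for e in exp)
    syy = sum((p - mean_pred) ** 2 for p in pred)
    sxy = sum((e - mean_exp) * (p - mean_pred) for e, p in zip(exp, pred))
    pearson_r2 = (sxy * sxy) / (sxx * syy) if sxx > 0 and syy > 0 else None
    return {"r2": r2, "rmse": rmse, "mae": mae, "pearson_r2": pearson_r2}


def _metrics_for(pairs, task_type: str, min_n: Optional[int] = None) -> dict:
    if task_type == REGRESSION:
        floor = MIN_N_REGRESSION if min_n is None else min_n
        if len(pairs) < floor:
            return {"r2": None, "rmse": None, "mae": None, "pearson_r2": None}
        return regression_metrics(pairs)
    floor = MIN_N_CLASSIFICATION if min_n is None else min_n
    if len(pairs) < floor:
        return {"accuracy": None}
    return classification_metrics(pairs)


def evaluate_model(
    kb: KnowledgeBase,
    model: ModelAdapter,
    test: Sequence[tuple[str, str, object]],
    config: Optional[ADIConfig] = None,
) -> StratifiedPerformance:
    """Assess each test compound's AD against the training-only KB and
    report per-stratum performance.

    Test compounds whose canonical SMILES occurs in the KB are excluded
    (structural, not id-based, duplicate detection): leaving them in would
    let the AD tool find the query itself among its neighbors and overstate
    reliability.  Unparsable test rows are excluded and listed as well.
    """
    if not test:
        raise ValueError("empty test set")
    if config is None:
        config = ADIConfig.for_task(model.task_type)
    kb_smiles = kb.canonical_smiles
    outcomes: list[PredictionOutcome] = []
    excluded: list[str] = []
    for mol_id, smiles, experimental in test:
        try:
            mol = parse_molecule(smiles, str(mol_id))
        except ParseError:
            excluded.append(str(mol_id))
            continue
        if mol.smiles_canonical in kb_smiles:
            excluded.append(str(mol_id))
            continue
        result = assess_compound(kb, model, mol, config)
        outcomes.append(
            PredictionOutcome(
                compound_id=str(mol_id),
                experimental=experimental,
                predicted=result.prediction,
                adi_result=result,
            )
        )
    strata: dict[str, dict] = {}
    for name in STRATA:
        pairs = [
            (o.experimental, o.predicted)
            for o in outcomes
            if o.adi_result.category == name
        ]
        strata[name] = {"n": len(pairs), "metrics": _metrics_for(pairs, model.task_type)}
    all_pairs = [(o.experimental, o.predicted) for o in outcomes]
    overall = {"n": len(all_pairs), "metrics": _metrics_for(all_pairs, model.task_type)}
    return StratifiedPerformance(
        task_type=model.task_type,
        strata=strata,
        overall=overall,
        outcomes=outcomes,
        excluded=excluded,
    )
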