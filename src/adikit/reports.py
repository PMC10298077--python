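"""Per-compound and batch report rendering.

The text report mirrors the parameter table a user sees alongside a
prediction — the overall ADI with its star category, each component index
at three decimal places, the ranked similar compounds, and the warnings.
Not-applicable entries render as "-".  The JSON form is a lossless
serialization: reloading it and re-rendering the text report reproduces
the text byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .adi import ADIConfig, ADIResult, assess_compound
from .chemspace import ParseError, parse_molecule
from .knowledge_base import NOT_APPLICABLE, KnowledgeBase

logger = logging.getLogger(__name__)


def result_to_dict(result: ADIResult) -> dict:
    c = result.components
    return {
        "target_id": result.target_id,
        "target_smiles": result.target_smiles,
        "prediction": result.prediction,
        "adi": result.adi,
        "category": result.category,
        "stars": result.stars,
        "components": {
            "similarity_index": c.similarity_index,
            "accuracy_index": c.accuracy_index,
            "concordance_index": c.concordance_index,
            "max_error_index": c.max_error_index,
            "acf_index": c.acf_index,
            "range_check": c.range_check,
            "range_violations": list(c.range_violations),
            "sensitivity_index": c.sensitivity_index,
            "outlier_fragment_hit": c.outlier_fragment_hit,
            "alert_concordance": c.alert_concordance,
        },
        "subscores": dict(result.subscores),
        "neighbors": [
            {
                "rank": n.rank,
                "id": n.record.molecule.id,
                "smiles": n.record.molecule.smiles_canonical,
                "similarity": n.similarity,
                "experimental": n.record.experimental,
                "predicted": n.record.predicted,
            }
            for n in result.neighbors
        ],
        "warnings": list(result.warnings),
    }


def _fmt(value, decimals: int = 3) -> str:
    if value is None or value == NOT_APPLICABLE:
        return "-"
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, (int, float)):
        return f"{float(value):.{decimals}f}"
    return str(value)


def render_text(doc: dict) -> str:
    """Render the dict form (see :func:`result_to_dict`) as the fixed-point
    parameter table."""
    c = doc["components"]
    lines = [
        f"ADI assessment: {doc['target_id']}  ({doc['target_smiles']})",
        f"Predicted value           {_fmt(doc['prediction'])}",
        "",
        f"ADI                       {_fmt(doc['adi'])}  [{doc['category']}, {'*' * doc['stars']}]",
        f"Similarity index          {_fmt(c['similarity_index'])}",
        f"Accuracy index            {_fmt(c['accuracy_index'])}",
        f"Concordance index         {_fmt(c['concordance_index'])}",
        f"Max error index           {_fmt(c['max_error_index'])}",
        f"Descriptors range check   {_fmt(c['range_check'])}",
        f"ACF index                 {_fmt(c['acf_index'])}",
        f"Sensitivity index         {_fmt(c['sensitivity_index'])}",
        "",
        f"Similar compounds ({len(doc['neighbors'])}):",
    ]
    for n in doc["neighbors"]:
        lines.append(
            f"  {n['rank']}. {n['id']}  similarity {_fmt(n['similarity'])}"
            f"  experimental {_fmt(n['experimental'])}  predicted {_fmt(n['predicted'])}"
        )
    if doc["warnings"]:
        lines.append("Warnings:")
        lines.extend(f"  - {w}" for w in doc["warnings"])
    else:
        lines.append("Warnings: none")
    return "\n".join(lines) + "\n"


def render_report(result: ADIResult, fmt: str = "text") -> str:
    """Render an assessment as ``text`` (3-decimal fixed point) or ``json``
    (full precision, lossless)."""
    doc = result_to_dict(result)
    if fmt == "json":
        return json.dumps(doc, indent=1, sort_keys=True)
    if fmt == "text":
        return render_text(doc)
    raise ValueError(f"unknown report format {fmt!r}")


# ---------------------------------------------------------------------------
# batch mode

BATCH_COLUMNS = [
    "id", "smiles", "prediction", "adi", "category", "stars",
    "similarity_index", "accuracy_index", "concordance_index",
    "max_error_index", "acf_index", "range_check", "sensitivity_index",
    "similarity_subscore", "accuracy_subscore", "concordance_subscore",
    "max_error_subscore", "acf_subscore", "sensitivity_subscore",
    "warnings", "error",
]


@dataclass
class BatchOutput:
    table: pd.DataFrame
    kept: pd.DataFrame
    filtered_out: Optional[pd.DataFrame]


def _row_from_result(mol_id: str, result: ADIResult) -> dict:
    doc = result_to_dict(result)
    c = doc["components"]
    row = {
        "id": mol_id,
        "smiles": doc["target_smiles"],
        "prediction": doc["prediction"],
        "adi": doc["adi"],
        "category": doc["category"],
        "stars": doc["stars"],
        "similarity_index": c["similarity_index"],
        "accuracy_index": c["accuracy_index"],
        "concordance_index": c["concordance_index"],
        "max_error_index": c["max_error_index"],
        "acf_index": c["acf_index"],
        "range_check": _fmt(c["range_check"]),
        "sensitivity_index": c["sensitivity_index"] if c["sensitivity_index"] != NOT_APPLICABLE else None,
        "warnings": "; ".join(doc["warnings"]),
        "error": "",
    }
    for name in ("similarity", "accuracy", "concordance", "max_error", "acf", "sensitivity"):
        row[f"{name}_subscore"] = doc["subscores"].get(name)
    return row


def run_batch(
    rows: list[tuple[str, str, object]],
    kb: KnowledgeBase,
    model,
    config: Optional[ADIConfig] = None,
    min_adi: Optional[float] = None,
) -> BatchOutput:
    """Assess every input compound, preserving input order.

    Unparsable compounds yield an error row instead of aborting the run.
    ``min_adi`` splits the table into kept rows (ADI >= threshold,
    inclusive) and a filtered-out remainder; error rows are never kept.
    """
    records = []
    for mol_id, smiles, _value in rows:
        try:
            mol = parse_molecule(smiles, str(mol_id))
            result = assess_compound(kb, model, mol, config)
            records.append(_row_from_result(str(mol_id), result))
        except (ParseError, ValueError) as exc:
            logger.warning("batch row %s failed: %s", mol_id, exc)
            rec = {col: None for col in BATCH_COLUMNS}
            rec.update({"id": str(mol_id), "smiles": smiles, "warnings": "", "error": str(exc)})
            records.append(rec)
    table = pd.DataFrame(records, columns=BATCH_COLUMNS)
    if min_adi is None:
        return BatchOutput(table=table, kept=table, filtered_out=None)
    ok = table["error"].fillna("").eq("") & table["adi"].notna() & (table["adi"] >= min_adi)
    return BatchOutput(table=table, kept=table[ok], filtered_out=table[~ok])


def write_batch(output: BatchOutput, path, write_all: bool = True) -> None:
    """Write the batch table; TSV when the extension is .tsv, CSV otherwise.
    With a ``min_adi`` filter active, the kept rows go to ``path`` and the
    remainder to a ``.filtered_out`` sidecar."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    if output.filtered_out is None:
        output.table.to_csv(path, sep=sep, index=False)
        return
    output.kept.to_csv(path, sep=sep, index=False)
    sidecar = path.with_suffix(path.suffix + ".filtered_out")
    output.filtered_out.to_csv(sidecar, sep=sep, index=False)
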