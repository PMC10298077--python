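"""The model's training knowledge: neighbor retrieval, ACF rarity, ranges.

A :class:`KnowledgeBase` indexes the wrapped model's training compounds
together with their experimental values and the model's own predictions for
them.  Applicability-domain scoring interrogates it three ways: nearest
neighbors by fingerprint similarity, how familiar the query's atom-centered
fragments are, and whether the query's descriptors fall inside the ranges
spanned by training compounds.

By default the knowledge base holds the training set only (the "modified
ADI" convention): restricting neighbor search to compounds that actually
built the model means a held-out test compound can never find itself among
its own neighbors, which would inflate every endpoint-dependent index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .chemspace import Molecule, ParseError, compute_similarity, parse_molecule

logger = logging.getLogger(__name__)

KB_FORMAT_VERSION = 1

SCOPE_TRAINING_ONLY = "training_only"
SCOPE_TRAINING_PLUS_TEST = "training_plus_test"

#: an ACF present in at least this many KB molecules counts as fully known
DEFAULT_F_KNOWN = 3
#: weight for ACFs seen in the KB but in fewer than ``f_known`` molecules
DEFAULT_W_RARE = 0.5


@dataclass
class TrainingRecord:
    molecule: Molecule
    experimental: object  # float for regression, label for classification
    predicted: object
    in_training: bool = True


@dataclass
class SimilarNeighbor:
    record: TrainingRecord
    similarity: float
    rank: int  # 1-based


@dataclass
class RejectedRecord:
    id: str
    smiles: str
    reason: str


@dataclass
class KnowledgeBase:
    records: list[TrainingRecord]
    acf_counts: dict[str, int]
    descriptor_ranges: dict[str, tuple[float, float]]
    task_type: str  # "regression" | "classification"
    scope: str = SCOPE_TRAINING_ONLY
    acf_weight: float = 0.0  # similarity blend weight, see chemspace
    rejects: list[RejectedRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def canonical_smiles(self) -> set[str]:
        return {r.molecule.smiles_canonical for r in self.records}


def _descriptor_ranges(records: Sequence[TrainingRecord]) -> dict[str, tuple[float, float]]:
    ranges: dict[str, tuple[float, float]] = {}
    mws = [r.molecule.molecular_weight for r in records]
    ranges["MW"] = (min(mws), max(mws))
    names: set[str] = set()
    for r in records:
        if r.molecule.descriptors:
            names.update(r.molecule.descriptors)
    for name in sorted(names):
        vals = [
            r.molecule.descriptors[name]
            for r in records
            if r.molecule.descriptors and name in r.molecule.descriptors
        ]
        ranges[name] = (min(vals), max(vals))
    return ranges


def _acf_counts(records: Sequence[TrainingRecord]) -> dict[str, int]:
    # molecule-level membership: each molecule contributes at most 1 per key
    counts: dict[str, int] = {}
    for r in records:
        for key in set(r.molecule.acfs):
            counts[key] = counts.get(key, 0) + 1
    return counts


def build_kb(
    records: Iterable[tuple[str, str, object]],
    model,
    scope: str = SCOPE_TRAINING_ONLY,
    acf_radius: int = 1,
    acf_weight: float = 0.0,
) -> KnowledgeBase:
    """Build a knowledge base from (id, smiles, experimental) rows.

    Every row is parsed, annotated with the model's descriptors (when the
    adapter exposes them) and with the model's own prediction.  Unparsable
    rows are skipped with a warning and listed in ``kb.rejects``; fewer than
    two usable rows is a fatal error.  The build is deterministic for fixed
    inputs.
    """
    if scope not in (SCOPE_TRAINING_ONLY, SCOPE_TRAINING_PLUS_TEST):
        raise ValueError(f"unknown scope {scope!r}")
    parsed: list[TrainingRecord] = []
    rejects: list[RejectedRecord] = []
    for mol_id, smiles, experimental in records:
        try:
            mol = parse_molecule(smiles, str(mol_id), acf_radius=acf_radius)
        except ParseError as exc:
            logger.warning("skipping record %s: %s", mol_id, exc.reason)
            rejects.append(RejectedRecord(str(mol_id), smiles, exc.reason))
            continue
        if model.descriptors is not None:
            mol = mol.with_descriptors(model.descriptors(mol))
        parsed.append(
            TrainingRecord(molecule=mol, experimental=experimental, predicted=model.predict(mol))
        )
    if len(parsed) < 2:
        raise ValueError(f"need at least 2 parsable records, got {len(parsed)}")
    return KnowledgeBase(
        records=parsed,
        acf_counts=_acf_counts(parsed),
        descriptor_ranges=_descriptor_ranges(parsed),
        task_type=model.task_type,
        scope=scope,
        acf_weight=acf_weight,
        rejects=rejects,
    )


def find_neighbors(
    kb: KnowledgeBase,
    target: Molecule,
    n_display: int = 6,
    exclude_self: bool = False,
) -> list[SimilarNeighbor]:
    """The ``n_display`` most similar KB compounds, ranked.

    Sorting is by similarity descending with ties broken by KB insertion
    order (stable), so rankings are fully deterministic.  A target that is
    structurally identical to a KB record appears at rank 1 with similarity
    1.0 unless ``exclude_self`` drops records with the target's canonical
    SMILES.
    """
    if not kb.records:
        raise ValueError("empty knowledge base")
    if n_display < 1:
        raise ValueError("n_display must be >= 1")
    candidates = [
        r for r in kb.records
        if not (exclude_self and r.molecule.smiles_canonical == target.smiles_canonical)
    ]
    scored = sorted(
        ((compute_similarity(target, r.molecule, kb.acf_weight), i, r)
         for i, r in enumerate(candidates)),
        key=lambda t: (-t[0], t[1]),
    )
    return [
        SimilarNeighbor(record=r, similarity=s, rank=rank)
        for rank, (s, _i, r) in enumerate(scored[:n_display], start=1)
    ]


def rank_all(kb: KnowledgeBase, target: Molecule, exclude_self: bool = False) -> list[SimilarNeighbor]:
    """Full similarity ranking of the KB (used so endpoint indices can
    promote past neighbors with missing experimental values)."""
    return find_neighbors(kb, target, n_display=len(kb.records), exclude_self=exclude_self)


NOT_APPLICABLE = "not_applicable"


def range_check(
    kb: KnowledgeBase,
    target: Molecule,
    descriptors: Optional[dict] = None,
    supported: bool = True,
) -> tuple[object, list[str]]:
    """Check target descriptors (always including MW) against KB ranges.

    Returns ``(True, [])`` when every supplied descriptor and the molecular
    weight lie within the [min, max] spanned by the KB, ``(False, names)``
    otherwise.  When the adapter declares range checking unsupported the
    result is ``(NOT_APPLICABLE, [])``, rendered "-" in reports.
    """
    if not supported:
        return NOT_APPLICABLE, []
    values = {"MW": target.molecular_weight}
    if descriptors:
        values.update(descriptors)
    violations = [
        name
        for name, v in values.items()
        if name in kb.descriptor_ranges
        and not (kb.descriptor_ranges[name][0] <= v <= kb.descriptor_ranges[name][1])
    ]
    return (len(violations) == 0), sorted(violations)


def acf_index(
    kb: KnowledgeBase,
    target: Molecule,
    f_known: int = DEFAULT_F_KNOWN,
    w_rare: float = DEFAULT_W_RARE,
) -> float:
    """How familiar the target's atom-centered fragments are to the KB.

    Each distinct target ACF scores 1 when at least ``f_known`` KB molecules
    contain it, ``w_rare`` when it is present but rare, and 0 when absent;
    the index is the mean over distinct fragments.  1.0 means no rare or
    unknown groups; 0.0 means fully alien chemistry.
    """
    keys = set(target.acfs)
    if not keys:
        raise ValueError("target has no ACFs")
    total = 0.0
    for key in keys:
        n = kb.acf_counts.get(key, 0)
        if n >= f_known:
            total += 1.0
        elif n >= 1:
            total += w_rare
    return total / len(keys)


# ---------------------------------------------------------------------------
# serialization: a single versioned JSON document

def kb_to_json(kb: KnowledgeBase) -> str:
    doc = {
        "format_version": KB_FORMAT_VERSION,
        "task_type": kb.task_type,
        "scope": kb.scope,
        "acf_weight": kb.acf_weight,
        "records": [
            {
                "id": r.molecule.id,
                "smiles": r.molecule.smiles_canonical,
                "experimental": r.experimental,
                "predicted": r.predicted,
                "in_training": r.in_training,
                "descriptors": r.molecule.descriptors,
                "fingerprint_hash": r.molecule.fingerprint_hash,
            }
            for r in kb.records
        ],
        "acf_counts": dict(sorted(kb.acf_counts.items())),
        "descriptor_ranges": {k: list(v) for k, v in sorted(kb.descriptor_ranges.items())},
        "rejects": [
            {"id": rj.id, "smiles": rj.smiles, "reason": rj.reason} for rj in kb.rejects
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def save_kb(kb: KnowledgeBase, path) -> None:
    with open(path, "w") as fh:
        fh.write(kb_to_json(kb))


def load_kb(path, acf_radius: int = 1) -> KnowledgeBase:
    """Reload a KB from its JSON form, re-deriving structures from the
    stored canonical SMILES and verifying fingerprint integrity."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != KB_FORMAT_VERSION:
        raise ValueError(f"unsupported KB format version {doc.get('format_version')!r}")
    records = []
    for rec in doc["records"]:
        mol = parse_molecule(rec["smiles"], rec["id"], acf_radius=acf_radius)
        if rec.get("descriptors"):
            mol = mol.with_descriptors(rec["descriptors"])
        if mol.fingerprint_hash != rec["fingerprint_hash"]:
            raise ValueError(f"fingerprint mismatch reloading record {rec['id']!r}")
        records.append(
            TrainingRecord(
                molecule=mol,
                experimental=rec["experimental"],
                predicted=rec["predicted"],
                in_training=rec.get("in_training", True),
            )
        )
    return KnowledgeBase(
        records=records,
        acf_counts={k: int(v) for k, v in doc["acf_counts"].items()},
        descriptor_ranges={k: (v[0], v[1]) for k, v in doc["descriptor_ranges"].items()},
        task_type=doc["task_type"],
        scope=doc["scope"],
        acf_weight=doc.get("acf_weight", 0.0),
        rejects=[RejectedRecord(**rj) for rj in doc.get("rejects", [])],
    )
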