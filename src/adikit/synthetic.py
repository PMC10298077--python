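"""Self-contained synthetic chemical space for building and testing.

Generates a training set plus three held-out test subsets with controlled
applicability-domain structure:

* ``test_in`` — held-out combinations of the *training* scaffolds and
  substituents: familiar chemistry, expected to land in the high-ADI
  stratum;
* ``test_edge`` — training scaffolds decorated with substituents never used
  in training: partially novel fragments, intermediate reliability;
* ``test_out`` — alien scaffolds (nitrosamines, organophosphates,
  sulfonamides) whose atom-centered fragments are absent from the training
  set entirely, mimicking the classic failure mode where a model is asked
  about chemistry it has never seen.

The simulated property is a smooth deterministic function of cheap
structural features (heavy-atom count, heteroatom fraction, molecular
weight) plus Gaussian noise in log units; the out-of-domain subset carries
a larger noise standard deviation, so a well-behaved AD tool should find
both lower ADI values and worse prediction statistics there.  No QSPR
realism is claimed — the space exists to make AD behavior observable and
reproducible, not to model an actual endpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .adi import ADIConfig, CLASSIFICATION, ComponentThreshold, HIGHER_BETTER, ModelAdapter, REGRESSION
from .chemspace import Molecule, compute_similarity, parse_molecule
from .evaluation import StratifiedPerformance, evaluate_model
from .knowledge_base import KnowledgeBase, build_kb

# one-slot scaffold templates used for training (and test_in/test_edge)
TRAIN_TEMPLATES = [
    "c1ccc({})cc1",          # benzene
    "c1cc({})ccn1",          # pyridine
    "C1CCC({})CC1",          # cyclohexane
    "CCCC{}",                # butyl chain
    "CC(C)C{}",              # isobutyl chain
    "c1ccc(O)c({})c1",       # phenol
    "c1ccc(cc1)C{}",         # benzyl
    "CCOCC{}",               # ethyl ether chain
]

# two-slot variants widen the pool so 250+ unique training-region compounds exist
TRAIN_TEMPLATES_2 = [
    "c1cc({0})ccc1{1}",      # para-disubstituted benzene
    "C1CC({0})CCC1{1}",      # 1,4-disubstituted cyclohexane
]

COMMON_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "C(C)C", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "Cl", "F", "C#N", "C(=O)C", "C(=O)OC", "C(=O)O", "CO",
    "CCO", "C=C", "CN", "OC(C)C",
]

# substituents reserved for test_edge: never attached in training
EDGE_SUBSTITUENTS = [
    "I", "Br", "C(F)(F)F", "C(=O)NC", "C#CC", "OC(=O)C", "CCl", "C(=O)N",
]

# alien scaffolds reserved for test_out; their core ACFs never occur in training
OUT_TEMPLATES = [
    "O=NN(C)C{}",            # nitrosamine
    "COP(=O)(OC)OC{}",       # organophosphate
    "O=S(=O)(N)c1ccc({})cc1",  # sulfonamide
]


@dataclass
class SpaceConfig:
    seed: int = 0
    n_train: int = 200
    n_test_in: int = 50
    n_test_edge: int = 40
    n_test_out: int = 30
    noise_sd: float = 0.2        # log units, training region
    noise_sd_out: float = 0.6    # log units, alien region
    train_templates: Sequence[str] = field(default_factory=lambda: list(TRAIN_TEMPLATES))
    train_templates_2: Sequence[str] = field(default_factory=lambda: list(TRAIN_TEMPLATES_2))
    common_substituents: Sequence[str] = field(default_factory=lambda: list(COMMON_SUBSTITUENTS))
    edge_substituents: Sequence[str] = field(default_factory=lambda: list(EDGE_SUBSTITUENTS))
    out_templates: Sequence[str] = field(default_factory=lambda: list(OUT_TEMPLATES))


@dataclass
class CompoundRecord:
    id: str
    smiles: str
    experimental: float
    subset: str  # train | test_in | test_edge | test_out

    def as_row(self) -> tuple[str, str, float]:
        return self.id, self.smiles, self.experimental


@dataclass
class SpaceData:
    config: SpaceConfig
    train: list[CompoundRecord]
    test: list[CompoundRecord]

    def test_rows(self) -> list[tuple[str, str, float]]:
        return [r.as_row() for r in self.test]

    def train_rows(self) -> list[tuple[str, str, float]]:
        return [r.as_row() for r in self.train]


def _clean_property(mol: Molecule) -> float:
    """Smooth deterministic property surface in pseudo log units."""
    rdmol = Chem.MolFromSmiles(mol.smiles_canonical)
    heavy = rdmol.GetNumHeavyAtoms()
    hetero = sum(1 for a in rdmol.GetAtoms() if a.GetSymbol() != "C")
    het_frac = hetero / heavy
    return 1.0 + 0.25 * heavy + 2.0 * het_frac + 0.002 * mol.molecular_weight


def _expand(templates: Sequence[str], subs: Sequence[str]) -> list[str]:
    return [t.format(s) for t in templates for s in subs]


def _expand2(templates: Sequence[str], subs: Sequence[str]) -> list[str]:
    return [t.format(a, b) for t in templates for a in subs for b in subs]


def _parse_pool(smiles_list: Sequence[str], taken: set[str]) -> list[Molecule]:
    """Parse candidates in order, dropping failures and canonical duplicates."""
    pool = []
    for smi in smiles_list:
        try:
            mol = parse_molecule(smi)
        except Exception:
            continue
        if mol.smiles_canonical in taken:
            continue
        taken.add(mol.smiles_canonical)
        pool.append(mol)
    return pool


def generate_space(config: Optional[SpaceConfig] = None) -> SpaceData:
    """Generate the train set and labeled test subsets.

    Deterministic for a fixed seed (a single ``numpy`` generator drives all
    stochastic draws).  By construction the train/test canonical-SMILES
    intersection is empty, every ``test_out`` compound carries at least one
    ACF unseen in training, and every emitted SMILES re-parses cleanly.
    """
    cfg = config or SpaceConfig()
    rng = np.random.default_rng(cfg.seed)
    taken: set[str] = set()

    train_pool = _parse_pool(
        _expand(cfg.train_templates, cfg.common_substituents)
        + _expand2(cfg.train_templates_2, cfg.common_substituents),
        taken,
    )
    need = cfg.n_train + cfg.n_test_in
    if len(train_pool) < need:
        raise ValueError(
            f"scaffold/substituent libraries too small: {len(train_pool)} unique "
            f"training-region compounds, need {need}"
        )
    order = rng.permutation(len(train_pool))
    train_mols = [train_pool[i] for i in order[: cfg.n_train]]
    in_mols = [train_pool[i] for i in order[cfg.n_train : need]]

    edge_pool = _parse_pool(_expand(cfg.train_templates, cfg.edge_substituents), taken)
    if len(edge_pool) < cfg.n_test_edge:
        raise ValueError(f"edge pool too small: {len(edge_pool)} < {cfg.n_test_edge}")
    edge_mols = [edge_pool[i] for i in rng.permutation(len(edge_pool))[: cfg.n_test_edge]]

    out_pool = _parse_pool(_expand(cfg.out_templates, cfg.common_substituents), taken)
    if len(out_pool) < cfg.n_test_out:
        raise ValueError(f"out pool too small: {len(out_pool)} < {cfg.n_test_out}")
    out_mols = [out_pool[i] for i in rng.permutation(len(out_pool))[: cfg.n_test_out]]

    def make_records(mols, subset, prefix, sd):
        noise = rng.normal(0.0, sd, size=len(mols))
        return [
            CompoundRecord(
                id=f"{prefix}-{i:04d}",
                smiles=m.smiles_canonical,
                experimental=float(_clean_property(m) + noise[i]),
                subset=subset,
            )
            for i, m in enumerate(mols, start=0)
        ]

    train = make_records(train_mols, "train", "train", cfg.noise_sd)
    test = (
        make_records(in_mols, "test_in", "in", cfg.noise_sd)
        + make_records(edge_mols, "test_edge", "edge", cfg.noise_sd)
        + make_records(out_mols, "test_out", "out", cfg.noise_sd_out)
    )
    return SpaceData(config=cfg, train=train, test=test)


# ---------------------------------------------------------------------------
# toy predictors


def _descriptor_vector(mol: Molecule) -> dict:
    rdmol = Chem.MolFromSmiles(mol.smiles_canonical)
    return {
        "heavy_atoms": float(rdmol.GetNumHeavyAtoms()),
        "heteroatoms": float(sum(1 for a in rdmol.GetAtoms() if a.GetSymbol() != "C")),
        "MW": float(mol.molecular_weight),
    }


def toy_model(
    train_records: Sequence[tuple[str, str, float]],
    task: str = REGRESSION,
    k: int = 3,
) -> ModelAdapter:
    """A deterministic k-nearest-neighbor predictor over fingerprint space.

    Regression: similarity-weighted mean of the k most similar training
    values (ties broken by training order; unweighted mean when all
    similarities are zero).  Classification: the same score thresholded at
    the training median, emitting labels 1 (above) / 0 (at or below).

    The adapter also exposes three scalar descriptors (heavy-atom count,
    heteroatom count, MW) and a least-squares linear descriptor head used
    for the perturbation-sensitivity check, so every ADI component is
    exercisable against it.
    """
    if len(train_records) < 5:
        raise ValueError("need at least 5 training records for the toy model")
    mols = [parse_molecule(smi, str(mid)) for mid, smi, _ in train_records]
    values = np.array([float(v) for _, _, v in train_records])

    def knn_value(target: Molecule) -> float:
        sims = np.array([compute_similarity(target, m) for m in mols])
        order = np.lexsort((np.arange(len(sims)), -sims))[:k]
        w = sims[order]
        if w.sum() <= 0:
            return float(values[order].mean())
        return float(np.dot(w, values[order]) / w.sum())

    # linear descriptor head (least squares) for the sensitivity check
    X = np.array([[1.0, *(_descriptor_vector(m)[n] for n in ("heavy_atoms", "heteroatoms", "MW"))] for m in mols])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    threshold = float(np.median(values))

    def from_descriptors(desc: dict) -> float:
        score = coef[0] + coef[1] * desc["heavy_atoms"] + coef[2] * desc["heteroatoms"] + coef[3] * desc["MW"]
        if task == CLASSIFICATION:
            return 1.0 if score > threshold else 0.0
        return float(score)

    if task == REGRESSION:
        predict = knn_value
    elif task == CLASSIFICATION:
        def predict(target: Molecule):
            return 1 if knn_value(target) > threshold else 0
    else:
        raise ValueError(f"unknown task {task!r}")

    return ModelAdapter(
        task_type=task,
        predict=predict,
        descriptors=_descriptor_vector,
        predict_from_descriptors=from_descriptors,
        name=f"toy-knn-{task}",
    )


#: model-specific ADI thresholds for the toy kNN predictor: Morgan/2048
#: Tanimoto between close analogs of small molecules rarely exceeds ~0.8,
#: so the similarity band is calibrated to that fingerprint rather than to
#: the library-wide log-unit defaults.
def benchmark_config(task: str = REGRESSION) -> ADIConfig:
    return ADIConfig.for_task(task).with_thresholds(
        similarity=ComponentThreshold(HIGHER_BETTER, 0.7, 0.3),
    )


@dataclass
class BenchmarkResult:
    space: SpaceData
    kb: KnowledgeBase
    performance: StratifiedPerformance
    mean_adi: dict[str, float]   # per test subset
    adi_by_compound: dict[str, float]


def benchmark_run(
    seed: int = 0,
    config: Optional[SpaceConfig] = None,
    task: str = REGRESSION,
    out_dir: Optional[Path] = None,
) -> BenchmarkResult:
    """End-to-end synthetic benchmark: generate space, fit the toy model,
    build the training-only KB, and evaluate AD-stratified performance.

    When ``out_dir`` is given, writes train/test CSVs, an SDF mirror, the
    generator config, and the stratified results (CSV + JSON).
    """
    cfg = config or SpaceConfig(seed=seed)
    if config is None:
        cfg.seed = seed
    space = generate_space(cfg)
    model = toy_model(space.train_rows(), task=task)
    kb = build_kb(space.train_rows(), model)
    adi_cfg = benchmark_config(task)
    perf = evaluate_model(kb, model, space.test_rows(), adi_cfg)

    subset_of = {r.id: r.subset for r in space.test}
    adi_by_compound = {o.compound_id: o.adi_result.adi for o in perf.outcomes}
    mean_adi = {}
    for subset in ("test_in", "test_edge", "test_out"):
        vals = [a for cid, a in adi_by_compound.items() if subset_of[cid] == subset]
        mean_adi[subset] = float(np.mean(vals)) if vals else float("nan")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_space(space, out_dir)
        perf.to_frame().to_csv(out_dir / "stratified_performance.csv", index=False)
        (out_dir / "stratified_performance.json").write_text(perf.to_json())
        (out_dir / "mean_adi_by_subset.json").write_text(json.dumps(mean_adi, indent=1))
    return BenchmarkResult(
        space=space, kb=kb, performance=perf, mean_adi=mean_adi, adi_by_compound=adi_by_compound
    )


def _write_space(space: SpaceData, out_dir: Path) -> None:
    import pandas as pd

    pd.DataFrame([asdict(r) for r in space.train]).to_csv(out_dir / "train.csv", index=False)
    pd.DataFrame([asdict(r) for r in space.test]).to_csv(out_dir / "test.csv", index=False)
    cfg = asdict(space.config)
    (out_dir / "space_config.json").write_text(json.dumps(cfg, indent=1, default=list))
    writer = Chem.SDWriter(str(out_dir / "compounds.sdf"))
    for rec in space.train + space.test:
        rdmol = Chem.MolFromSmiles(rec.smiles)
        rdmol.SetProp("_Name", rec.id)
        rdmol.SetProp("experimental", f"{rec.experimental:.4f}")
        rdmol.SetProp("subset", rec.subset)
        writer.write(rdmol)
    writer.close()
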