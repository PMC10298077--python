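import pytest

from adikit.adi import ModelAdapter, REGRESSION
from adikit.chemspace import parse_molecule
from adikit.knowledge_base import build_kb


# ten simple compounds with made-up log-unit property values
TEN_COMPOUNDS = [
    ("m01", "CCO", 1.0),
    ("m02", "CCCO", 1.2),
    ("m03", "CCCCO", 1.4),
    ("m04", "c1ccccc1", 2.0),
    ("m05", "Cc1ccccc1", 2.1),
    ("m06", "CCc1ccccc1", 2.2),
    ("m07", "CCN", 0.8),
    ("m08", "CCCN", 0.9),
    ("m09", "CC(C)O", 1.1),
    ("m10", "CCOC", 1.3),
]


def exact_model(rows, task=REGRESSION, offset=0.0, **adapter_kwargs):
    """Adapter predicting each known structure's experimental value (+offset);
    unknown structures get the training mean.  Deterministic by table lookup."""
    table = {}
    values = []
    for _, smiles, value in rows:
        can = parse_molecule(smiles).smiles_canonical
        table[can] = value
        values.append(value)
    if task == REGRESSION:
        fallback = sum(values) / len(values)

        def predict(mol):
            return table.get(mol.smiles_canonical, fallback) + offset
    else:
        fallback = max(set(values), key=values.count)

        def predict(mol):
            return table.get(mol.smiles_canonical, fallback)

    return ModelAdapter(task_type=task, predict=predict, **adapter_kwargs)


@pytest.fixture(scope="session")
def ten_molecules():
    return [parse_molecule(s, i) for i, s, _ in TEN_COMPOUNDS]


@pytest.fixture()
def ten_kb():
    return build_kb(TEN_COMPOUNDS, exact_model(TEN_COMPOUNDS))


@pytest.fixture(scope="session")
def default_benchmark():
    """One full-size synthetic benchmark run, shared across tests."""
    from adikit.synthetic import benchmark_run

    return benchmark_run(seed=0)
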