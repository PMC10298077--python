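"""Readers for compound inputs: CSV, SDF (V2000), and plain SMILES lists.

All readers return ``(id, smiles, experimental)`` tuples; ``experimental``
is ``None`` when no value column/property is requested.  Parsing of the
structures themselves happens downstream so that bad SMILES can be
reported per row instead of aborting a whole file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
from rdkit import Chem

Row = tuple[str, str, object]


def read_compounds_csv(
    path,
    id_col: str = "id",
    smiles_col: str = "smiles",
    value_col: Optional[str] = "experimental",
) -> list[Row]:
    df = pd.read_csv(path)
    for col in (id_col, smiles_col):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path} (have {list(df.columns)})")
    has_value = value_col is not None and value_col in df.columns
    rows: list[Row] = []
    for _, rec in df.iterrows():
        value = rec[value_col] if has_value else None
        if has_value and pd.isna(value):
            value = None
        rows.append((str(rec[id_col]), str(rec[smiles_col]), value))
    return rows


def read_compounds_sdf(path, value_prop: Optional[str] = None) -> list[Row]:
    """Read a V2000 SDF; id from the title line (falling back to a running
    index), optional experimental value from a named property tag."""
    rows: list[Row] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            rows.append((f"record-{i}", "", None))
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record-{i}"
        value = None
        if value_prop and mol.HasProp(value_prop):
            raw = mol.GetProp(value_prop)
            try:
                value = float(raw)
            except ValueError:
                value = raw
        rows.append((mol_id, Chem.MolToSmiles(mol), value))
    return rows


def read_smiles_list(path) -> list[Row]:
    """One SMILES per line, optionally followed by whitespace and an id."""
    rows: list[Row] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"record-{i}"
        rows.append((mol_id, smiles, None))
    return rows


def read_compounds(path, value_col: Optional[str] = "experimental",
                   value_prop: Optional[str] = None) -> list[Row]:
    """Dispatch on file extension: .csv, .sdf, else SMILES list."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return read_compounds_csv(path, value_col=value_col)
    if suffix == ".sdf":
        return read_compounds_sdf(path, value_prop=value_prop or value_col)
    return read_smiles_list(path)
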