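"""Structure handling for applicability-domain assessment.

SMILES parsing and canonicalization, circular fingerprints, Tanimoto
similarity, and atom-centered fragment (ACF) extraction.  Everything in
this module is a deterministic function of the canonical SMILES, so that
knowledge-base compounds and query compounds are always compared under a
single aromaticity and hydrogen convention.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from collections import Counter
from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.DataStructs.cDataStructs import ExplicitBitVect, TanimotoSimilarity

RDLogger.DisableLog("rdApp.*")

FP_RADIUS = 2
FP_BITS = 2048

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)

# bond-order symbols used inside ACF keys; aromatic bonds get ':'
_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


class ParseError(ValueError):
    """A SMILES string that could not be turned into a Molecule.

    Carries the offending input and the compound id so that batch runs can
    report per-row failures without aborting.
    """

    def __init__(self, smiles: str, mol_id: str, reason: str):
        self.smiles = smiles
        self.mol_id = mol_id
        self.reason = reason
        super().__init__(f"cannot parse SMILES for '{mol_id}': {reason} (input: {smiles!r})")


class MultiFragmentError(ParseError):
    """Multi-fragment SMILES (salt/mixture) rejected by default.

    Applicability-domain semantics for mixtures are undefined; pass
    ``keep_largest_fragment=True`` to strip counter-ions instead.
    """

    def __init__(self, smiles: str, mol_id: str):
        super().__init__(smiles, mol_id, "multi-fragment SMILES (salt or mixture)")


@dataclass(frozen=True)
class Molecule:
    """A parsed structure with everything AD scoring needs precomputed.

    ``fingerprint`` is a Morgan (circular, radius 2) bit vector folded to
    2048 bits; ``acfs`` is the multiset of atom-centered fragment keys, one
    entry per heavy atom; ``descriptors`` holds model-supplied scalar
    descriptors when an adapter provides them.
    """

    id: str
    smiles_input: str
    smiles_canonical: str
    heavy_atom_count: int
    molecular_weight: float
    fingerprint: ExplicitBitVect = field(compare=False, repr=False)
    acfs: Counter = field(compare=False, repr=False)
    descriptors: Optional[dict] = field(default=None, compare=False)

    @property
    def fingerprint_bits(self) -> frozenset:
        """The set of on-bit indices (handy for independent set arithmetic)."""
        return frozenset(self.fingerprint.GetOnBits())

    @property
    def fingerprint_hash(self) -> str:
        """Short stable digest of the on-bit set (serialization integrity)."""
        payload = ",".join(map(str, sorted(self.fingerprint.GetOnBits())))
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def with_descriptors(self, descriptors: dict) -> "Molecule":
        return Molecule(
            id=self.id,
            smiles_input=self.smiles_input,
            smiles_canonical=self.smiles_canonical,
            heavy_atom_count=self.heavy_atom_count,
            molecular_weight=self.molecular_weight,
            fingerprint=self.fingerprint,
            acfs=self.acfs,
            descriptors=dict(descriptors),
        )


def _atom_center(atom: Chem.Atom) -> str:
    charge = atom.GetFormalCharge()
    arom = "a" if atom.GetIsAromatic() else ""
    return f"{atom.GetSymbol()}{charge:+d}{arom}H{atom.GetTotalNumHs()}"


def _radius1_key(atom: Chem.Atom) -> str:
    shell = sorted(
        _BOND_SYMBOL[b.GetBondType()] + _atom_neighbor_label(b.GetOtherAtom(atom))
        for b in atom.GetBonds()
    )
    return _atom_center(atom) + "(" + ",".join(shell) + ")"


def _atom_neighbor_label(atom: Chem.Atom) -> str:
    arom = "a" if atom.GetIsAromatic() else ""
    return f"{atom.GetSymbol()}{arom}"


def extract_acfs(mol: Chem.Mol, radius: int = 1) -> Counter:
    """Atom-centered fragment keys for every heavy atom of ``mol``.

    A radius-1 key records the central atom (element, formal charge,
    aromaticity, total hydrogen count) and the canonically sorted list of
    (bond order, heavy-neighbor element) pairs; a radius-2 key nests each
    neighbor's own radius-1 key. Keys are invariant to atom input order, so
    two SMILES renderings of one structure give identical multisets.
    """
    if radius not in (1, 2):
        raise ValueError(f"ACF radius must be 1 or 2, got {radius}")
    r1 = {a.GetIdx(): _radius1_key(a) for a in mol.GetAtoms()}
    keys = []
    for atom in mol.GetAtoms():
        if radius == 1:
            keys.append(r1[atom.GetIdx()])
        else:
            shell = sorted(
                _BOND_SYMBOL[b.GetBondType()] + "[" + r1[b.GetOtherAtom(atom).GetIdx()] + "]"
                for b in atom.GetBonds()
            )
            keys.append(_atom_center(atom) + "{" + ",".join(shell) + "}")
    return Counter(keys)


def parse_molecule(
    smiles: str,
    mol_id: str = "",
    acf_radius: int = 1,
    keep_largest_fragment: bool = False,
) -> Molecule:
    """Parse a SMILES string into a fully featurized :class:`Molecule`.

    Parsing is strict: valence errors, unclosed rings and empty input raise
    :class:`ParseError`. Multi-fragment inputs (salts, mixtures) raise
    :class:`MultiFragmentError` unless ``keep_largest_fragment`` is set, in
    which case the fragment with the most heavy atoms is kept.
    """
    if not smiles or not smiles.strip():
        raise ParseError(smiles, mol_id, "empty SMILES")
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ParseError(smiles, mol_id, "RDKit rejected the SMILES")
    frags = Chem.GetMolFrags(rdmol, asMols=True)
    if len(frags) > 1:
        if not keep_largest_fragment:
            raise MultiFragmentError(smiles, mol_id)
        rdmol = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    if rdmol.GetNumHeavyAtoms() < 1:
        raise ParseError(smiles, mol_id, "no heavy atoms")
    canonical = Chem.MolToSmiles(rdmol)
    return Molecule(
        id=mol_id,
        smiles_input=smiles,
        smiles_canonical=canonical,
        heavy_atom_count=rdmol.GetNumHeavyAtoms(),
        molecular_weight=float(Descriptors.MolWt(rdmol)),
        fingerprint=_FP_GEN.GetFingerprint(rdmol),
        acfs=extract_acfs(rdmol, radius=acf_radius),
    )


def compute_similarity(a: Molecule, b: Molecule, acf_weight: float = 0.0) -> float:
    """Structural similarity in [0, 1]; 1.0 for identical structures.

    Default is the Tanimoto (Jaccard) coefficient over the Morgan/2048
    fingerprints. ``acf_weight`` in (0, 1] blends in the Jaccard coefficient
    of the two ACF key sets:

        sim = (1 - w) * tanimoto_fp + w * jaccard_acf

    The blend preserves symmetry, the [0, 1] range, and identity at 1.
    """
    fp_sim = TanimotoSimilarity(a.fingerprint, b.fingerprint)
    if acf_weight <= 0.0:
        return float(fp_sim)
    sa, sb = set(a.acfs), set(b.acfs)
    union = len(sa | sb)
    acf_sim = (len(sa & sb) / union) if union else 1.0
    return float((1.0 - acf_weight) * fp_sim + acf_weight * acf_sim)
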