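"""SMILES parsing, physicochemical descriptors, and Morgan fingerprints.

All chemistry is delegated to RDKit. The descriptor conventions follow the
classical Lipinski counting scheme rather than pharmacophore perception:

* HBD = number of N-H plus O-H hydrogens (``nOH + nNH``),
* HBA = number of nitrogen plus oxygen atoms (``nO + nN``),
* logP = Wildman-Crippen atom-contribution estimate,
* TPSA = Ertl fragment-additive topological polar surface area,
* rotatable bonds = strict definition (amide C-N bonds excluded).

Multi-fragment inputs (salts) are reduced to the largest organic fragment
before any descriptor is computed, so counterions never inflate Mw or HBA.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator, rdMolDescriptors

from .errors import ConfigurationError, ParseError

RDLogger.DisableLog("rdApp.*")

#: Canonical descriptor column order used everywhere downstream.
DESCRIPTOR_KEYS = (
    "mw",
    "logp",
    "hbd",
    "hba",
    "tpsa",
    "n_rotb",
    "n_carbon",
    "n_hetero",
    "n_rings",
)

#: Names of the estimators behind each computed descriptor, recorded in
#: dataset provenance because platform discrepancies (notably logP and TPSA)
#: are a known source of violation-count disagreement.
DESCRIPTOR_ESTIMATORS = {
    "mw": "rdkit.MolWt (average mass)",
    "logp": "rdkit.Crippen.MolLogP (Wildman-Crippen)",
    "tpsa": "rdkit.TPSA (Ertl)",
    "n_rotb": "rdkit.CalcNumRotatableBonds (strict)",
}

#: Element set of the Muegge composition screen (optional, off by default).
MUEGGE_ELEMENTS = frozenset({"C", "N", "O", "S", "H", "P", "Si", "Cl", "Br", "F", "I"})


@dataclass(frozen=True)
class MoleculeRecord:
    """A named SMILES entry as read from a ``.smi`` or CSV file."""

    id: str
    smiles: str
    name: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("molecule id must be non-empty")
        if not self.smiles:
            raise ValueError(f"molecule {self.id!r} has an empty SMILES")


@dataclass(frozen=True)
class DescriptorVector:
    """The nine-descriptor physicochemical profile every rule operates on."""

    mw: float
    logp: float
    hbd: int
    hba: int
    tpsa: float
    n_rotb: int
    n_carbon: int
    n_hetero: int
    n_rings: int

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in DESCRIPTOR_KEYS], dtype=float)


@dataclass(frozen=True)
class FingerprintVector:
    """A hashed circular-substructure (Morgan/ECFP-like) bit vector."""

    bits: np.ndarray
    radius: int
    n_bits: int

    def __post_init__(self):
        if len(self.bits) != self.n_bits:
            raise ValueError("bit vector length does not match n_bits")

    @property
    def n_on(self) -> int:
        return int(np.sum(self.bits))


def parse_molecule(smiles: str, molecule_id: str | None = None) -> Chem.Mol:
    """Parse and sanitize a SMILES string.

    Salts and other multi-fragment inputs are reduced to the largest organic
    (carbon-containing) fragment. Raises :class:`ParseError` naming the
    offending molecule id on unparsable or valence-invalid input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError("empty SMILES", molecule_id)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}", molecule_id)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
        pool = organic or list(frags)
        mol = max(pool, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))
        Chem.SanitizeMol(mol)
    return mol


def canonical_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def compute_descriptors(mol: Chem.Mol, molecule_id: str | None = None) -> DescriptorVector:
    """Compute the full nine-field descriptor vector for a parsed molecule."""
    try:
        return DescriptorVector(
            mw=float(Descriptors.MolWt(mol)),
            logp=float(Crippen.MolLogP(mol)),
            hbd=int(Lipinski.NHOHCount(mol)),
            hba=int(Lipinski.NOCount(mol)),
            tpsa=float(Descriptors.TPSA(mol)),
            n_rotb=int(
                rdMolDescriptors.CalcNumRotatableBonds(
                    mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
                )
            ),
            n_carbon=sum(a.GetAtomicNum() == 6 for a in mol.GetAtoms()),
            n_hetero=sum(a.GetAtomicNum() not in (1, 6) for a in mol.GetAtoms()),
            n_rings=int(rdMolDescriptors.CalcNumRings(mol)),
        )
    except Exception as exc:  # pragma: no cover - exotic-element descriptor failures
        raise ParseError(f"descriptor computation failed: {exc}", molecule_id) from exc


def element_screen(mol: Chem.Mol, allowed: frozenset[str] = MUEGGE_ELEMENTS) -> bool:
    """True if every atom belongs to the allowed element set."""
    return all(a.GetSymbol() in allowed for a in mol.GetAtoms())


def morgan_fingerprint(mol: Chem.Mol, radius: int = 2, n_bits: int = 2048) -> FingerprintVector:
    """Hashed Morgan fingerprint as a 0/1 vector of length ``n_bits``."""
    if n_bits <= 0:
        raise ConfigurationError(f"n_bits must be positive, got {n_bits}")
    if radius < 0:
        raise ConfigurationError(f"radius must be >= 0, got {radius}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    fp = gen.GetFingerprint(mol)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return FingerprintVector(bits=arr, radius=radius, n_bits=n_bits)


# ---------------------------------------------------------------------------
# File IO


def read_smi(path: str | Path) -> list[MoleculeRecord]:
    """Read a ``.smi`` file: one molecule per line, ``SMILES [id]``."""
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"mol{i:05d}"
        records.append(MoleculeRecord(id=mol_id, smiles=smiles))
    return records


def read_molecule_csv(path: str | Path) -> list[MoleculeRecord]:
    """Read a CSV with a mandatory ``smiles`` column, optional ``id``/``name``."""
    df = pd.read_csv(path, dtype=str)
    if "smiles" not in df.columns:
        raise ConfigurationError(f"{path}: CSV must contain a 'smiles' column")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        mol_id = getattr(row, "id", None) or f"mol{i:05d}"
        name = getattr(row, "name", None)
        records.append(
            MoleculeRecord(id=str(mol_id), smiles=str(row.smiles), name=None if pd.isna(name) else name)
        )
    return records


def read_molecules(path: str | Path) -> list[MoleculeRecord]:
    """Dispatch on extension: ``.smi`` or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_molecule_csv(path)
    return read_smi(path)


def descriptor_table(
    records: Sequence[MoleculeRecord],
) -> tuple[pd.DataFrame, list[tuple[MoleculeRecord, str]]]:
    """Compute descriptors for a batch of molecules.

    Returns ``(table, rejects)`` where rejects lists ``(record, reason)`` for
    parse failures; failures are reported, never silently dropped.
    """
    rows, rejects = [], []
    for rec in records:
        try:
            mol = parse_molecule(rec.smiles, rec.id)
            dv = compute_descriptors(mol, rec.id)
        except ParseError as exc:
            rejects.append((rec, str(exc)))
            continue
        rows.append({"id": rec.id, "smiles": rec.smiles, **dv.as_dict()})
    cols = ["id", "smiles", *DESCRIPTOR_KEYS]
    return pd.DataFrame(rows, columns=cols), rejects


def write_descriptor_csv(records: Sequence[MoleculeRecord], path: str | Path) -> list[tuple[MoleculeRecord, str]]:
    """Write the descriptor CSV (``id,smiles,mw,...,n_rings``); returns rejects."""
    table, rejects = descriptor_table(records)
    table.to_csv(path, index=False)
    return rejects
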