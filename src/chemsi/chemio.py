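"""Structure and dataset input.

Molecules are stored as hydrogen-depleted graphs (implicit H counts on the
heavy atoms), the convention used by all downstream keys. Parsing is done by
RDKit; the :class:`Molecule` container keeps an explicit atom/bond table so
that the rest of the package has a stable, backend-independent view, plus a
lazily built RDKit handle for substructure matching.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


class StructureParseError(ValueError):
    """Raised when a SMILES string or SDF block cannot be parsed."""


class DatasetError(ValueError):
    """Raised when a property dataset file is malformed.

    ``row_errors`` carries (row number, message) pairs so a caller can report
    every offending record at once.
    """

    def __init__(self, message: str, row_errors: Sequence[tuple[int, str]] = ()):
        super().__init__(message)
        self.row_errors = list(row_errors)


@dataclass(frozen=True)
class Atom:
    symbol: str
    charge: int
    aromatic: bool
    n_hydrogens: int


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int  # 1, 2 or 3; aromatic bonds carry order 1 + aromatic flag
    aromatic: bool


@dataclass
class Molecule:
    """Hydrogen-depleted molecular graph.

    Invariants (checked in :func:`parse_structure`): at least one heavy atom,
    bond endpoints valid and distinct, no duplicate bonds, and every aromatic
    bond joins two aromatic atoms.
    """

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    source_smiles: str
    _rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)

    def to_rdkit(self) -> Chem.Mol:
        """RDKit handle (sanitised, aromaticity perceived), built lazily."""
        if self._rdmol is None:
            mol = Chem.MolFromSmiles(self.source_smiles)
            if mol is None:  # pragma: no cover - source_smiles is canonical
                raise StructureParseError(
                    f"internal: cannot rebuild RDKit mol for {self.id!r}"
                )
            self._rdmol = mol
        return self._rdmol

    def write_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())


@dataclass
class PropertyDataset:
    """Compounds with one numeric endpoint value each (log units)."""

    records: list[tuple[str, Molecule, float]]
    endpoint_name: str = "value"

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate compound ids: {dupes}")
        for cid, _mol, value in self.records:
            if not _is_finite(value):
                raise DatasetError(f"non-finite value for compound {cid!r}")
        if len(self.records) < 4:
            raise DatasetError(
                "dataset needs at least 4 compounds (3 neighbours + 1 query), "
                f"got {len(self.records)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def molecules(self) -> list[Molecule]:
        return [r[1] for r in self.records]

    @property
    def values(self) -> list[float]:
        return [r[2] for r in self.records]


def _is_finite(x: float) -> bool:
    return x == x and x not in (float("inf"), float("-inf"))


def _largest_fragment(mol: Chem.Mol, record_id: str) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    warnings.warn(
        f"{record_id}: dot-disconnected input; keeping largest fragment",
        stacklevel=3,
    )
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def _from_rdkit(mol: Chem.Mol, record_id: str) -> Molecule:
    if mol.GetNumHeavyAtoms() < 1:
        raise StructureParseError(f"{record_id}: no heavy atoms")
    atoms = [
        Atom(
            symbol=a.GetSymbol(),
            charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            n_hydrogens=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        aromatic = b.GetIsAromatic()
        order = 1 if aromatic else int(b.GetBondTypeAsDouble())
        bonds.append(
            Bond(i=b.GetBeginAtomIdx(), j=b.GetEndAtomIdx(), order=order, aromatic=aromatic)
        )
        if aromatic and not (atoms[b.GetBeginAtomIdx()].aromatic and atoms[b.GetEndAtomIdx()].aromatic):
            raise StructureParseError(f"{record_id}: aromatic bond on non-aromatic atom")
    return Molecule(
        id=record_id,
        atoms=atoms,
        bonds=bonds,
        source_smiles=Chem.MolToSmiles(mol),
        _rdmol=mol,
    )


def parse_structure(text: str, record_id: str = "mol") -> Molecule:
    """Parse a SMILES string or a single SDF/MOL V2000 block.

    Aromaticity is perceived; hydrogens are kept implicit. Dot-disconnected
    inputs (salts/mixtures) are reduced to the largest fragment by heavy-atom
    count with a warning. Stereochemistry is accepted but ignored downstream.
    """
    if not text.strip():
        raise StructureParseError(f"{record_id}: empty structure")
    if "\n" in text or "M  END" in text:
        mol = Chem.MolFromMolBlock(text, sanitize=True)  # keep header lines intact
        kind = "SDF block"
    else:
        text = text.strip()
        mol = Chem.MolFromSmiles(text)
        kind = "SMILES"
    if mol is None:
        raise StructureParseError(f"{record_id}: cannot parse {kind} {text!r:.80}")
    mol = _largest_fragment(mol, record_id)
    Chem.SanitizeMol(mol)
    return _from_rdkit(mol, record_id)


def read_smiles_file(path: str | Path) -> list[Molecule]:
    """One SMILES per line, optional whitespace-separated id."""
    molecules = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"mol{lineno}"
        molecules.append(parse_structure(smiles, record_id=mol_id))
    return molecules


def read_dataset(
    path: str | Path,
    endpoint_name: str = "value",
    on_error: str = "strict",
) -> PropertyDataset:
    """Read a CSV/TSV property dataset with header columns id, smiles, value.

    Parameters
    ----------
    on_error:
        ``"strict"`` (default) raises :class:`DatasetError` listing every bad
        row; ``"skip"`` drops bad rows with a logged warning.
    """
    if on_error not in ("strict", "skip"):
        raise ValueError(f"on_error must be 'strict' or 'skip', got {on_error!r}")
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"dataset file not found: {path}")
    text = path.read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    fields = [f.strip().lower() for f in (reader.fieldnames or [])]
    missing = {"id", "smiles", "value"} - set(fields)
    if missing:
        raise DatasetError(f"{path}: missing required column(s) {sorted(missing)}")

    records: list[tuple[str, Molecule, float]] = []
    row_errors: list[tuple[int, str]] = []
    seen: set[str] = set()
    for rowno, row in enumerate(reader, start=2):  # row 1 is the header
        row = {k.strip().lower(): (v or "").strip() for k, v in row.items() if k}
        cid = row.get("id", "")
        try:
            if not cid:
                raise DatasetError("empty id")
            if cid in seen:
                raise DatasetError(f"duplicate id {cid!r}")
            try:
                value = float(row.get("value", ""))
            except ValueError:
                raise DatasetError(f"non-numeric value {row.get('value')!r}") from None
            if not _is_finite(value):
                raise DatasetError(f"non-finite value {value!r}")
            mol = parse_structure(row.get("smiles", ""), record_id=cid)
        except (DatasetError, StructureParseError) as exc:
            row_errors.append((rowno, str(exc)))
            continue
        seen.add(cid)
        records.append((cid, mol, value))

    if row_errors:
        if on_error == "strict":
            detail = "; ".join(f"row {n}: {m}" for n, m in row_errors)
            raise DatasetError(f"{path}: {len(row_errors)} bad row(s): {detail}", row_errors)
        for rowno, msg in row_errors:
            logger.warning("%s: skipped row %d: %s", path, rowno, msg)
    return PropertyDataset(records=records, endpoint_name=endpoint_name)


def write_dataset(dataset: PropertyDataset, path: str | Path) -> None:
    """Write the standard id,smiles,value CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "value"])
        for cid, mol, value in dataset.records:
            writer.writerow([cid, mol.source_smiles, repr(value)])


def molecules_from_smiles(pairs: Iterable[tuple[str, str]]) -> list[Molecule]:
    """Convenience: build molecules from (id, smiles) pairs."""
    return [parse_structure(smi, record_id=cid) for cid, smi in pairs]
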