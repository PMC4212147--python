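"""Pattern catalogs backing the structural-key fingerprints and the FG key.

Two sources:

* **Shipped TSV files** (``data/*.tsv``, format ``index<TAB>SMARTS<TAB>name``)
  for the E-state atom-type key (79 entries) and the functional-group
  occurrence key (154 entries). Both are authored for this package and
  user-replaceable via :func:`load_catalog`.

* **Synthetic generated catalogs** for the maccs / substructure / pubchem /
  klekota_roth key families. The published definitions of those keys are
  third-party data and are not redistributed here; instead a deterministic
  enumerator produces fixed-length stand-in catalogs of simple linear-chain
  SMARTS (lengths 1-4 over common organic elements). The family contract -
  ``bit i = 1 iff pattern i matches`` at the family's fixed length - is
  preserved; the individual bit meanings are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

from rdkit import Chem


class CatalogError(ValueError):
    """Raised when a pattern catalog is missing or contains invalid SMARTS."""


@dataclass(frozen=True)
class CatalogEntry:
    index: int
    smarts: str
    name: str

    @property
    def pattern(self) -> Chem.Mol:
        return _compile(self.smarts)


@lru_cache(maxsize=None)
def _compile(smarts: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise CatalogError(f"invalid SMARTS {smarts!r}")
    return patt


def _parse_tsv(text: str, source: str) -> list[CatalogEntry]:
    entries: list[CatalogEntry] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise CatalogError(f"{source}:{lineno}: expected index<TAB>SMARTS[<TAB>name]")
        try:
            index = int(parts[0])
        except ValueError:
            raise CatalogError(f"{source}:{lineno}: bad index {parts[0]!r}") from None
        smarts = parts[1].strip()
        if Chem.MolFromSmarts(smarts) is None:
            raise CatalogError(f"{source}:{lineno}: invalid SMARTS {smarts!r} (pattern {index})")
        name = parts[2].strip() if len(parts) > 2 else ""
        entries.append(CatalogEntry(index=index, smarts=smarts, name=name))
    if not entries:
        raise CatalogError(f"{source}: empty catalog")
    expected = list(range(1, len(entries) + 1))
    if [e.index for e in entries] != expected:
        raise CatalogError(f"{source}: indices must run 1..{len(entries)} without gaps")
    return entries


def load_catalog(path: str | Path) -> list[CatalogEntry]:
    """Load a user-supplied catalog TSV (``index<TAB>SMARTS<TAB>name``)."""
    path = Path(path)
    if not path.exists():
        raise CatalogError(f"catalog file not found: {path}")
    return _parse_tsv(path.read_text(encoding="utf-8"), str(path))


@lru_cache(maxsize=None)
def packaged_catalog(name: str) -> tuple[CatalogEntry, ...]:
    """Load a catalog shipped with the package (``estate_keys``, ``functional_groups``)."""
    try:
        text = (resources.files("chemsi") / "data" / f"{name}.tsv").read_text(encoding="utf-8")
    except FileNotFoundError:
        raise CatalogError(f"packaged catalog {name!r} not found") from None
    return tuple(_parse_tsv(text, f"chemsi/data/{name}.tsv"))


# ---------------------------------------------------------------------------
# synthetic catalog enumeration
# ---------------------------------------------------------------------------

_CHAIN_ATOMS = ["C", "N", "O", "S", "P", "B", "F", "Cl", "Br", "I", "c", "n", "o", "s"]
_AROMATIC = {"c", "n", "o", "s"}
_TERMINAL_ONLY = {"F", "Cl", "Br", "I"}
_BONDS = ["-", "=", "#", ":", "~"]


def _bond_allowed(a1: str, a2: str, bond: str) -> bool:
    if bond == "~":
        return True
    if bond == ":":
        return a1 in _AROMATIC and a2 in _AROMATIC
    if a1 in _AROMATIC or a2 in _AROMATIC:
        return bond == "-"
    if bond == "=":
        return a1 not in _TERMINAL_ONLY and a2 not in _TERMINAL_ONLY
    if bond == "#":
        return a1 in {"C", "N"} and a2 in {"C", "N"}
    return True  # single bond


def _enumerate_chains(n_atoms: int):
    """Yield canonical linear-chain SMARTS with ``n_atoms`` atoms, in a fixed order."""
    if n_atoms == 1:
        for a in _CHAIN_ATOMS:
            yield a
        return

    def rec(atoms: list[str], bonds: list[str]):
        if len(atoms) == n_atoms:
            forward = atoms[0] + "".join(b + a for b, a in zip(bonds, atoms[1:]))
            rev_atoms, rev_bonds = atoms[::-1], bonds[::-1]
            backward = rev_atoms[0] + "".join(b + a for b, a in zip(rev_bonds, rev_atoms[1:]))
            if forward <= backward:  # canonical orientation only
                yield forward
            return
        last = atoms[-1]
        interior = len(atoms) < n_atoms - 1
        for bond in _BONDS:
            for atom in _CHAIN_ATOMS:
                if interior and atom in _TERMINAL_ONLY:
                    continue
                if last in _TERMINAL_ONLY and len(atoms) > 1:
                    continue  # halogen already mid-chain (cannot happen, safety)
                if not _bond_allowed(last, atom, bond):
                    continue
                yield from rec(atoms + [atom], bonds + [bond])

    for first in _CHAIN_ATOMS:
        start_terminal_ok = True  # first atom may be terminal halogen
        if start_terminal_ok:
            yield from rec([first], [])


@lru_cache(maxsize=None)
def synthetic_key_catalog(family: str, size: int) -> tuple[CatalogEntry, ...]:
    """Deterministic synthetic stand-in catalog of ``size`` linear-chain SMARTS.

    The enumeration order is fixed (chain length 1 upward, fixed alphabet
    order), so the same ``size`` always yields the same catalog on every
    platform and run. All emitted SMARTS are RDKit-valid.
    """
    entries: list[CatalogEntry] = []
    seen: set[str] = set()
    n_atoms = 1
    while len(entries) < size:
        if n_atoms > 6:
            raise CatalogError(
                f"synthetic enumeration exhausted at {len(entries)} < {size} patterns"
            )
        for smarts in _enumerate_chains(n_atoms):
            if smarts in seen:
                continue
            if Chem.MolFromSmarts(smarts) is None:  # pragma: no cover - all chains valid
                continue
            seen.add(smarts)
            entries.append(
                CatalogEntry(index=len(entries) + 1, smarts=smarts, name=f"{family} synthetic chain")
            )
            if len(entries) == size:
                break
        n_atoms += 1
    return tuple(entries)
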