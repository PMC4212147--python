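"""The nine fingerprint / structural-key families, behind a provider registry.

Hashed families (``default``, ``extended``, ``graph_only``, ``hybridization``)
enumerate every simple linear path of 0-7 bonds in the heavy-atom graph,
build a canonical path string from element symbols and bond-order symbols,
and hash each string onto a fixed-length bit vector:

* ``default``      - aromaticity-perceived bond symbols ``- = # :``
* ``extended``     - ``default`` plus an appended 14-bit ring-feature block
                     (presence of ring sizes 3-8, unary SSSR ring count <= 8)
* ``graph_only``   - path strings drop the bond symbols entirely
* ``hybridization``- Kekule bond orders (no aromatic bond symbol)

Hashing is ``blake2b`` (8-byte digest) of the path string reduced modulo the
bit length; it is fixed, documented, and stable across platforms and runs.
No attempt is made to reproduce CDK's hash values bit-for-bit - the contract
is family semantics.

Key families (``estate``, ``maccs``, ``pubchem``, ``substructure``,
``klekota_roth``) evaluate an ordered SMARTS catalog: bit ``i-1`` is set iff
catalog pattern ``i`` matches at least once. ``estate`` ships a 79-entry
atom-type catalog; the other four use deterministic synthetic stand-in
catalogs at the family's published length (see :mod:`chemsi.catalogs`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from rdkit import Chem

from chemsi.catalogs import CatalogEntry, packaged_catalog, synthetic_key_catalog
from chemsi.chemio import Molecule

MAX_PATH_BONDS = 7

KEY_FAMILY_LENGTHS = {
    "estate": 79,
    "maccs": 166,
    "substructure": 307,
    "pubchem": 881,
    "klekota_roth": 4860,
}

DEFAULT_HASHED_LENGTH = 1024
RING_BLOCK_BITS = 14  # sizes 3..8 (6 bits) + unary SSSR count capped at 8


class FingerprintError(ValueError):
    """Unknown fingerprint type or configuration problem."""


@dataclass(frozen=True)
class FingerprintType:
    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise FingerprintError(f"fingerprint length must be positive, got {self.length}")


@dataclass(frozen=True)
class BitFingerprint:
    type: FingerprintType
    set_bits: tuple[int, ...]

    def __post_init__(self) -> None:
        bits = tuple(sorted(set(self.set_bits)))
        object.__setattr__(self, "set_bits", bits)
        if bits and not (0 <= bits[0] and bits[-1] < self.type.length):
            raise FingerprintError(
                f"bit positions out of range [0, {self.type.length}) for {self.type.name}"
            )

    def __len__(self) -> int:
        return self.type.length


# ---------------------------------------------------------------------------
# hashed path families
# ---------------------------------------------------------------------------

def _path_hash(path: str, length: int, k: int) -> list[int]:
    bits = []
    for j in range(k):
        digest = hashlib.blake2b(f"{path}|{j}".encode(), digest_size=8).digest()
        bits.append(int.from_bytes(digest, "big") % length)
    return bits


_BOND_SYMBOL = {1.0: "-", 2.0: "=", 3.0: "#", 1.5: ":"}


def _enumerate_paths(mol: Chem.Mol, use_bond_orders: bool) -> set[str]:
    """Canonical strings of all simple linear paths of 0..MAX_PATH_BONDS bonds."""
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    bond_sym: dict[tuple[int, int], str] = {}
    adjacency: dict[int, list[int]] = {i: [] for i in range(mol.GetNumAtoms())}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        sym = _BOND_SYMBOL.get(b.GetBondTypeAsDouble(), "-")
        bond_sym[(i, j)] = bond_sym[(j, i)] = sym
        adjacency[i].append(j)
        adjacency[j].append(i)

    paths: set[str] = set()

    def path_string(atom_path: list[int]) -> str:
        if use_bond_orders:
            fwd = symbols[atom_path[0]] + "".join(
                bond_sym[(u, v)] + symbols[v] for u, v in zip(atom_path, atom_path[1:])
            )
            rev_path = atom_path[::-1]
            rev = symbols[rev_path[0]] + "".join(
                bond_sym[(u, v)] + symbols[v] for u, v in zip(rev_path, rev_path[1:])
            )
        else:
            fwd = "".join(symbols[i] for i in atom_path)
            rev = fwd[::-1] if all(len(symbols[i]) == 1 for i in atom_path) else "".join(
                symbols[i] for i in atom_path[::-1]
            )
        return min(fwd, rev)

    def dfs(atom_path: list[int], visited: set[int]) -> None:
        paths.add(path_string(atom_path))
        if len(atom_path) > MAX_PATH_BONDS:
            return
        for nxt in adjacency[atom_path[-1]]:
            if nxt not in visited:
                dfs(atom_path + [nxt], visited | {nxt})

    for start in range(mol.GetNumAtoms()):
        dfs([start], {start})
    return paths


def _ring_block_bits(mol: Chem.Mol, base: int) -> list[int]:
    ring_sizes = {len(r) for r in mol.GetRingInfo().AtomRings()}
    bits = [base + size - 3 for size in ring_sizes if 3 <= size <= 8]
    n_rings = min(len(mol.GetRingInfo().AtomRings()), 8)
    bits.extend(base + 6 + i for i in range(n_rings))
    return bits


@dataclass
class HashedPathProvider:
    """Daylight-style linear-path fingerprint over the heavy-atom graph."""

    name: str
    length: int = DEFAULT_HASHED_LENGTH
    use_bond_orders: bool = True
    kekulize: bool = False
    ring_block: bool = False
    bits_per_path: int = 1
    _cache: dict[str, BitFingerprint] = field(default_factory=dict, repr=False)

    @property
    def fingerprint_type(self) -> FingerprintType:
        total = self.length + (RING_BLOCK_BITS if self.ring_block else 0)
        return FingerprintType(name=self.name, length=total)

    def _prepared_mol(self, molecule: Molecule) -> Chem.Mol:
        mol = molecule.to_rdkit()
        if self.kekulize:
            mol = Chem.Mol(mol)
            Chem.Kekulize(mol, clearAromaticFlags=True)
        return mol

    def compute(self, molecule: Molecule) -> BitFingerprint:
        key = molecule.source_smiles
        if key not in self._cache:
            bits = {
                b
                for path in _enumerate_paths(self._prepared_mol(molecule), self.use_bond_orders)
                for b in _path_hash(path, self.length, self.bits_per_path)
            }
            if self.ring_block:
                bits.update(_ring_block_bits(molecule.to_rdkit(), self.length))
            self._cache[key] = BitFingerprint(self.fingerprint_type, tuple(bits))
        return self._cache[key]

    def explain(self, molecule: Molecule) -> dict[int, list[str]]:
        """Debug trace: bit index -> contributing path strings / ring features."""
        trace: dict[int, list[str]] = {}
        for path in sorted(_enumerate_paths(self._prepared_mol(molecule), self.use_bond_orders)):
            for b in _path_hash(path, self.length, self.bits_per_path):
                trace.setdefault(b, []).append(path)
        if self.ring_block:
            for b in _ring_block_bits(molecule.to_rdkit(), self.length):
                trace.setdefault(b, []).append(f"ring-feature:{b - self.length}")
        return trace


# ---------------------------------------------------------------------------
# structural key families
# ---------------------------------------------------------------------------

@dataclass
class KeyCatalogProvider:
    """Ordered-SMARTS structural key: bit i-1 = pattern i matches at least once."""

    name: str
    entries: tuple[CatalogEntry, ...]
    _cache: dict[str, BitFingerprint] = field(default_factory=dict, repr=False)

    @property
    def fingerprint_type(self) -> FingerprintType:
        return FingerprintType(name=self.name, length=len(self.entries))

    def compute(self, molecule: Molecule) -> BitFingerprint:
        key = molecule.source_smiles
        if key not in self._cache:
            mol = molecule.to_rdkit()
            bits = tuple(
                e.index - 1 for e in self.entries if mol.HasSubstructMatch(e.pattern)
            )
            self._cache[key] = BitFingerprint(self.fingerprint_type, bits)
        return self._cache[key]

    def explain(self, molecule: Molecule) -> dict[int, list[str]]:
        mol = molecule.to_rdkit()
        return {
            e.index - 1: [e.smarts]
            for e in self.entries
            if mol.HasSubstructMatch(e.pattern)
        }


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _build_default_registry() -> dict[str, object]:
    registry: dict[str, object] = {
        "default": HashedPathProvider("default"),
        "extended": HashedPathProvider("extended", ring_block=True),
        "graph_only": HashedPathProvider("graph_only", use_bond_orders=False),
        "hybridization": HashedPathProvider("hybridization", kekulize=True),
        "estate": KeyCatalogProvider("estate", tuple(packaged_catalog("estate_keys"))),
    }
    for family in ("maccs", "substructure", "pubchem", "klekota_roth"):
        registry[family] = KeyCatalogProvider(
            family, synthetic_key_catalog(family, KEY_FAMILY_LENGTHS[family])
        )
    return registry


_REGISTRY: dict[str, object] | None = None


def _registry() -> dict[str, object]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _build_default_registry()
    return _REGISTRY


def register_provider(provider) -> None:
    """Register a user plugin provider (must expose fingerprint_type/compute)."""
    _registry()[provider.fingerprint_type.name] = provider


def get_provider(name: str):
    try:
        return _registry()[name]
    except KeyError:
        known = ", ".join(sorted(_registry()))
        raise FingerprintError(f"unknown fingerprint type {name!r}; known: {known}") from None


def list_available_types() -> list[FingerprintType]:
    return [p.fingerprint_type for p in _registry().values()]


def compute_fingerprint(molecule: Molecule, fp_type: str | FingerprintType) -> BitFingerprint:
    name = fp_type.name if isinstance(fp_type, FingerprintType) else fp_type
    return get_provider(name).compute(molecule)
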