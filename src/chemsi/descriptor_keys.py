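"""Non-binary structural keys: constitutional descriptors (CD), hetero-atom
counters (HD) and functional-group occurrence counts (FG).

The CD key holds 35 zero-dimensional descriptors (atom/bond counts plus sums
and heavy-atom means of carbon-scaled atomic constants). The HD key is the
11-counter hetero-atom subset of CD, split out so it can receive its own
weight in the similarity index. The FG key counts occurrences (not booleans)
of each entry of a 154-pattern SMARTS catalog - occurrence counting is what
lets the index see "two hydroxyls" where a fingerprint sees only "hydroxyl".

Conventions: hydrogen-depleted graph with implicit H counts; aromatic bonds
contribute 1.5 to SCBO; Sv/Sp/Se sum over heavy atoms only and Mv/Mp/Me
divide by the heavy-atom count; atomic constants are carbon-scaled and read
from ``data/atomic_constants.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from chemsi.catalogs import CatalogEntry, packaged_catalog
from chemsi.chemio import Molecule

HALOGENS = ("F", "Cl", "Br", "I")

CD_FIELDS = (
    "MW", "AMW", "Sv", "Mv", "Sp", "Mp", "Se", "Me", "nAt", "nSk", "nBt",
    "nBo", "nBm", "nDblBo", "nTrpBo", "nArBo", "SCBO", "nH", "nC", "nN",
    "nO", "nP", "nS", "nF", "nCl", "nBr", "nI", "nB", "HPerc", "CPerc",
    "NPerc", "OPerc", "XPerc", "nHet", "nX",
)

HD_FIELDS = ("nN", "nO", "nP", "nS", "nF", "nCl", "nBr", "nI", "nB", "nHet", "nX")


class DescriptorError(ValueError):
    """Raised when a descriptor cannot be computed (e.g. missing constants)."""


@dataclass(frozen=True)
class AtomConstants:
    """Per-element atomic constants: mass (u) and carbon-scaled van der Waals
    volume, Sanderson electronegativity and polarizability."""

    mass: dict[str, float]
    vdw_volume: dict[str, float]
    sanderson_en: dict[str, float]
    polarizability: dict[str, float]

    @classmethod
    def from_tsv(cls, text: str) -> "AtomConstants":
        mass, vdw, en, pol = {}, {}, {}, {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("element"):
                continue
            element, *values = line.split("\t")
            m, v, e, p = (float(x) for x in values)
            mass[element], vdw[element], en[element], pol[element] = m, v, e, p
        return cls(mass, vdw, en, pol)

    @classmethod
    def from_file(cls, path: str | Path) -> "AtomConstants":
        return cls.from_tsv(Path(path).read_text(encoding="utf-8"))

    def require(self, element: str) -> None:
        if element not in self.mass:
            raise DescriptorError(
                f"element {element!r} missing from the atomic constants table"
            )


@lru_cache(maxsize=1)
def default_constants() -> AtomConstants:
    text = (resources.files("chemsi") / "data" / "atomic_constants.tsv").read_text(
        encoding="utf-8"
    )
    return AtomConstants.from_tsv(text)


@dataclass(frozen=True)
class ConstitutionalKey:
    """The 35-descriptor constitutional key (field order is the key order)."""

    MW: float
    AMW: float
    Sv: float
    Mv: float
    Sp: float
    Mp: float
    Se: float
    Me: float
    nAt: int
    nSk: int
    nBt: int
    nBo: int
    nBm: int
    nDblBo: int
    nTrpBo: int
    nArBo: int
    SCBO: float
    nH: int
    nC: int
    nN: int
    nO: int
    nP: int
    nS: int
    nF: int
    nCl: int
    nBr: int
    nI: int
    nB: int
    HPerc: float
    CPerc: float
    NPerc: float
    OPerc: float
    XPerc: float
    nHet: int
    nX: int

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in CD_FIELDS], dtype=float)


@dataclass(frozen=True)
class HeteroKey:
    """The 11 hetero-atom counters (a subset of the constitutional key)."""

    nN: int
    nO: int
    nP: int
    nS: int
    nF: int
    nCl: int
    nBr: int
    nI: int
    nB: int
    nHet: int
    nX: int

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in HD_FIELDS], dtype=float)


@dataclass(frozen=True)
class FunctionalGroupKey:
    """Occurrence counts, one per catalog entry (counts, not booleans)."""

    counts: tuple[int, ...]

    def as_vector(self) -> np.ndarray:
        return np.array(self.counts, dtype=float)

    def __len__(self) -> int:
        return len(self.counts)


def compute_cd(molecule: Molecule, constants: AtomConstants | None = None) -> ConstitutionalKey:
    constants = constants or default_constants()
    for atom in molecule.atoms:
        constants.require(atom.symbol)
    constants.require("H")

    element_counts: dict[str, int] = {}
    for atom in molecule.atoms:
        element_counts[atom.symbol] = element_counts.get(atom.symbol, 0) + 1

    n_sk = len(molecule.atoms)
    n_h = sum(a.n_hydrogens for a in molecule.atoms)
    n_at = n_sk + n_h
    n_bo = len(molecule.bonds)
    n_bt = n_bo + n_h

    n_dbl = sum(1 for b in molecule.bonds if b.order == 2 and not b.aromatic)
    n_trp = sum(1 for b in molecule.bonds if b.order == 3)
    n_ar = sum(1 for b in molecule.bonds if b.aromatic)
    scbo = sum(1.5 if b.aromatic else float(b.order) for b in molecule.bonds)

    mw = n_h * constants.mass["H"] + sum(constants.mass[a.symbol] for a in molecule.atoms)
    sv = sum(constants.vdw_volume[a.symbol] for a in molecule.atoms)
    sp = sum(constants.polarizability[a.symbol] for a in molecule.atoms)
    se = sum(constants.sanderson_en[a.symbol] for a in molecule.atoms)

    def count(sym: str) -> int:
        return element_counts.get(sym, 0)

    n_x = sum(count(h) for h in HALOGENS)
    n_het = n_sk - count("C")

    return ConstitutionalKey(
        MW=mw,
        AMW=mw / n_at,
        Sv=sv,
        Mv=sv / n_sk,
        Sp=sp,
        Mp=sp / n_sk,
        Se=se,
        Me=se / n_sk,
        nAt=n_at,
        nSk=n_sk,
        nBt=n_bt,
        nBo=n_bo,
        nBm=n_dbl + n_trp + n_ar,
        nDblBo=n_dbl,
        nTrpBo=n_trp,
        nArBo=n_ar,
        SCBO=scbo,
        nH=n_h,
        nC=count("C"),
        nN=count("N"),
        nO=count("O"),
        nP=count("P"),
        nS=count("S"),
        nF=count("F"),
        nCl=count("Cl"),
        nBr=count("Br"),
        nI=count("I"),
        nB=count("B"),
        HPerc=100.0 * n_h / n_at,
        CPerc=100.0 * count("C") / n_at,
        NPerc=100.0 * count("N") / n_at,
        OPerc=100.0 * count("O") / n_at,
        XPerc=100.0 * n_x / n_at,
        nHet=n_het,
        nX=n_x,
    )


def compute_hd(molecule: Molecule) -> HeteroKey:
    cd = compute_cd(molecule)
    return HeteroKey(**{f: getattr(cd, f) for f in HD_FIELDS})


@lru_cache(maxsize=1)
def default_fg_catalog() -> tuple[CatalogEntry, ...]:
    return tuple(packaged_catalog("functional_groups"))


def compute_fg(
    molecule: Molecule, catalog: tuple[CatalogEntry, ...] | None = None
) -> FunctionalGroupKey:
    """Count distinct matches of each catalog pattern (matched-atom sets are
    deduplicated, so symmetric SMARTS do not double-count)."""
    catalog = catalog if catalog is not None else default_fg_catalog()
    mol = molecule.to_rdkit()
    counts = tuple(
        len(mol.GetSubstructMatches(entry.pattern, uniquify=True)) for entry in catalog
    )
    return FunctionalGroupKey(counts=counts)
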