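"""Similarity coefficients and the combined similarity index (SI).

The SI of two molecules A, B is a weighted combination of one binary
fingerprint similarity and three non-binary key similarities::

    SI(A,B) = Sb(FP_a,FP_b)^w_fp * Snb(CD_a,CD_b)^w_cd
              * Snb(HD_a,HD_b)^w_hd * Snb(FG_a,FG_b)^w_fg

with w_fp + w_cd + w_hd + w_fg = 1. The product form (a weighted geometric
mean) is the default; a weighted arithmetic mean is available as a config
switch for sensitivity analysis.

Binary coefficients
-------------------
The 44 binary coefficients follow the Todeschini et al. (2012) roster and
keep its numbering; the algebraic forms are transcribed per entry below
(``source`` notes). Conventions applied uniformly:

* (b, c) are canonicalised to (min, max) before evaluation, which makes the
  few orientation-dependent forms (Dice 1/2, Peirce 1/2, Cole 1/2) symmetric
  and is a no-op for the rest.
* raw range [-1, 1]  ->  rescaled (s+1)/2
* raw range [0, inf) ->  mapped s/(1+s)
* raw range [0, p]   ->  divided by p (Harris-Lahey)
* everything clipped to [0, 1] (guards the Cole forms, whose raw values can
  leave [-1, 1])

Degenerate-input policy: identical all-zero fingerprints -> 1; identical
inputs -> 1 for every coefficient whose formula attains its maximum at
identity (the ``self_unit`` flag); otherwise an undefined (0/0) value maps
to 0.5 for correlation-type coefficients and 0 for the rest. Nine roster
coefficients (Russell-Rao, Forbes, Faith, Michael, Fossum, Dennis,
Dispersion, CT3, CT5) do not equal 1 on identical inputs by construction;
they carry ``self_unit=False``.

Non-binary coefficients
-----------------------
The six non-binary coefficients (Holliday et al. numbering) operate on
nonnegative real vectors; the three distance forms (Mean Canberra,
Divergence, Bray-Curtis) are returned as complements of the normalised
distance. 0/0 component terms contribute 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from chemsi.chemio import Molecule
from chemsi.descriptor_keys import compute_cd, compute_fg, compute_hd
from chemsi.fingerprints import BitFingerprint, compute_fingerprint

WEIGHT_TOLERANCE = 1e-9


class SimilarityError(ValueError):
    """Unknown coefficient id, weight violation, or malformed input."""


# ---------------------------------------------------------------------------
# confusion counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of bit positions set in both (a), first only (b), second only
    (c), and neither (d) of two equal-length fingerprints."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise SimilarityError("confusion counts must be nonnegative")

    @property
    def p(self) -> int:
        return self.a + self.b + self.c + self.d


def confusion_counts(x: BitFingerprint, y: BitFingerprint) -> ConfusionCounts:
    if x.type.length != y.type.length or x.type.name != y.type.name:
        raise SimilarityError(
            f"fingerprint type mismatch: {x.type.name}/{x.type.length} vs "
            f"{y.type.name}/{y.type.length}"
        )
    sx, sy = set(x.set_bits), set(y.set_bits)
    a = len(sx & sy)
    b = len(sx - sy)
    c = len(sy - sx)
    return ConfusionCounts(a=a, b=b, c=c, d=x.type.length - a - b - c)


# ---------------------------------------------------------------------------
# binary coefficient registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryCoefficient:
    id: int
    name: str
    raw_range: str  # 'unit', 'pm1', 'pos_inf', 'zero_p', or a custom tag
    self_unit: bool
    correlation: bool  # undefined 0/0 -> 0.5 instead of 0
    raw: Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    source: str = ""

    def evaluate(self, a, b, c, d) -> np.ndarray:
        """Vectorized [0,1] similarity from confusion-count arrays."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        c = np.asarray(c, dtype=float)
        d = np.asarray(d, dtype=float)
        b, c = np.minimum(b, c), np.maximum(b, c)  # canonical orientation
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = self.raw(a, b, c, d)
            value = _TRANSFORMS[self.raw_range](raw, a, b, c, d)
        identical = (b == 0) & (c == 0)
        undefined = ~np.isfinite(value)
        value = np.where(undefined, np.where(identical, 1.0, 0.5 if self.correlation else 0.0), value)
        if self.self_unit:
            value = np.where(identical, 1.0, value)
        value = np.where(identical & (a == 0), 1.0, value)  # identical all-zero
        return np.clip(value, 0.0, 1.0)


def _p(a, b, c, d):
    return a + b + c + d


_TRANSFORMS = {
    "unit": lambda s, a, b, c, d: s,
    "pm1": lambda s, a, b, c, d: (s + 1.0) / 2.0,
    "pos_inf": lambda s, a, b, c, d: s / (1.0 + s),
    "zero_p": lambda s, a, b, c, d: s / _p(a, b, c, d),
    "dennis": lambda s, a, b, c, d: (s + np.sqrt(_p(a, b, c, d)) / 2.0)
    / (1.5 * np.sqrt(_p(a, b, c, d))),
    "dispersion": lambda s, a, b, c, d: 2.0 * s + 0.5,
}


def _term(num, den, fill):
    """num/den with 0-denominator entries replaced by ``fill``."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.divide(num, den, out=np.full(np.broadcast(num, den).shape, float(fill)), where=den != 0)
    return out


def _rogot_goldberg(a, b, c, d):
    return _term(a, 2 * a + b + c, 0.5) + _term(d, 2 * d + b + c, 0.5)


def _hawkins_dotson(a, b, c, d):
    return 0.5 * (_term(a, a + b + c, 1.0) + _term(d, d + b + c, 1.0))


def _sokal_sneath_4(a, b, c, d):
    identical = (b == 0) & (c == 0)
    fill = np.where(identical, 1.0, 0.0)
    total = np.zeros(np.broadcast(a, d).shape)
    for num, den in ((a, a + b), (a, a + c), (d, d + b), (d, d + c)):
        total = total + np.where(
            np.asarray(den, dtype=float) != 0,
            _term(num, den, 0.0),
            fill,
        )
    return 0.25 * total


def _harris_lahey(a, b, c, d):
    return _term(a * (2 * d + b + c), 2 * (a + b + c), 0.0) + _term(
        d * (2 * a + b + c), 2 * (b + c + d), 0.0
    )


_TODESCHINI = "Todeschini et al. 2012 roster (JCIM 52:2884), entry {}"

BINARY_COEFFICIENTS: dict[int, BinaryCoefficient] = {}


def _register(id_, name, raw_range, self_unit, correlation, raw, note=""):
    BINARY_COEFFICIENTS[id_] = BinaryCoefficient(
        id=id_,
        name=name,
        raw_range=raw_range,
        self_unit=self_unit,
        correlation=correlation,
        raw=raw,
        source=(_TODESCHINI.format(id_) + ("; " + note if note else "")),
    )


_register(1, "Simple matching", "unit", True, False, lambda a, b, c, d: (a + d) / _p(a, b, c, d))
_register(2, "Rogers/Tanimoto", "unit", True, False, lambda a, b, c, d: (a + d) / (_p(a, b, c, d) + b + c))
_register(3, "Jaccard/Tanimoto", "unit", True, False, lambda a, b, c, d: a / (a + b + c))
_register(4, "Gleason/Dice/Sorensen/Nei-Li", "unit", True, False, lambda a, b, c, d: 2 * a / (2 * a + b + c))
_register(5, "Russel-Rao", "unit", False, False, lambda a, b, c, d: a / _p(a, b, c, d),
          "value on identical inputs is a/p < 1 by construction")
_register(6, "Forbes", "pos_inf", False, False,
          lambda a, b, c, d: a * _p(a, b, c, d) / ((a + b) * (a + c)),
          "raw range [0, p]; bounded via s/(1+s)")
_register(7, "Simpson", "unit", True, False, lambda a, b, c, d: a / np.minimum(a + b, a + c))
_register(8, "Braun-Blanquet", "unit", True, False, lambda a, b, c, d: a / np.maximum(a + b, a + c))
_register(9, "Driver-Kroeber/Ochiai", "unit", True, False,
          lambda a, b, c, d: a / np.sqrt((a + b) * (a + c)))
_register(10, "Baroni-Urbani 1", "unit", True, False,
          lambda a, b, c, d: (np.sqrt(a * d) + a) / (np.sqrt(a * d) + a + b + c))
_register(11, "Kulczynski 1", "pos_inf", True, False, lambda a, b, c, d: a / (b + c))
_register(12, "Sokal-Sneath 1", "unit", True, False, lambda a, b, c, d: a / (a + 2 * (b + c)))
_register(13, "Sokal-Sneath 2", "unit", True, False,
          lambda a, b, c, d: 2 * (a + d) / (_p(a, b, c, d) + a + d))
_register(14, "Jaccard 2", "unit", True, False, lambda a, b, c, d: 3 * a / (3 * a + b + c),
          "weighted Jaccard variant 3a/(3a+b+c)")
_register(15, "Faith", "unit", False, False, lambda a, b, c, d: (a + 0.5 * d) / _p(a, b, c, d))
_register(16, "Mountford", "pos_inf", True, False,
          lambda a, b, c, d: 2 * a / (a * b + a * c + 2 * b * c))
_register(17, "Michael", "pm1", False, True,
          lambda a, b, c, d: 4 * (a * d - b * c) / ((a + d) ** 2 + (b + c) ** 2))
_register(18, "Rogot-Goldberg", "unit", True, False, _rogot_goldberg)
_register(19, "Hawkins-Dotson", "unit", True, False, _hawkins_dotson)
_register(20, "Yule 1", "pm1", True, True,
          lambda a, b, c, d: (a * d - b * c) / (a * d + b * c))
_register(21, "Yule 2", "pm1", True, True,
          lambda a, b, c, d: (np.sqrt(a * d) - np.sqrt(b * c)) / (np.sqrt(a * d) + np.sqrt(b * c)))
_register(22, "Fossum", "pos_inf", False, False,
          lambda a, b, c, d: _p(a, b, c, d) * (a - 0.5) ** 2 / ((a + b) * (a + c)))
_register(23, "Dennis", "dennis", False, True,
          lambda a, b, c, d: (a * d - b * c) / np.sqrt(_p(a, b, c, d) * (a + b) * (a + c)),
          "raw range [-sqrt(p)/2, sqrt(p)]; shifted/scaled accordingly")
_register(24, "Cole 1", "pm1", True, True,
          lambda a, b, c, d: (a * d - b * c) / ((a + b) * (b + d)),
          "raw can leave [-1,1]; clipped")
_register(25, "Cole 2", "pm1", True, True,
          lambda a, b, c, d: (a * d - b * c) / ((a + c) * (c + d)),
          "raw can leave [-1,1]; clipped")
_register(26, "Dispersion", "dispersion", False, True,
          lambda a, b, c, d: (a * d - b * c) / _p(a, b, c, d) ** 2,
          "raw range [-1/4, 1/4]")
_register(27, "Goodman-Kruskal", "pm1", True, True,
          lambda a, b, c, d: (2 * np.minimum(a, d) - b - c) / (2 * np.minimum(a, d) + b + c))
_register(28, "Sokal-Sneath 3", "pos_inf", True, False, lambda a, b, c, d: (a + d) / (b + c))
_register(29, "Sokal-Sneath 4", "unit", True, False, _sokal_sneath_4)
_register(30, "Phi", "pm1", True, True,
          lambda a, b, c, d: (a * d - b * c) / np.sqrt((a + b) * (a + c) * (b + d) * (c + d)))
_register(31, "Dice 1", "unit", True, False, lambda a, b, c, d: a / (a + b),
          "orientation-dependent; evaluated on canonical (min,max) margins")
_register(32, "Dice 2", "unit", True, False, lambda a, b, c, d: a / (a + c),
          "orientation-dependent; evaluated on canonical (min,max) margins")
_register(33, "Sorgenfrei", "unit", True, False, lambda a, b, c, d: a ** 2 / ((a + b) * (a + c)))
_register(34, "Cohen", "pm1", True, True,
          lambda a, b, c, d: 2 * (a * d - b * c) / ((a + b) * (b + d) + (a + c) * (c + d)))
_register(35, "Peirce 1", "pm1", True, True,
          lambda a, b, c, d: (a * d - b * c) / ((a + b) * (c + d)),
          "orientation-dependent; evaluated on canonical (min,max) margins")
_register(36, "Peirce 2", "pm1", True, True,
          lambda a, b, c, d: (a * d - b * c) / ((a + c) * (b + d)),
          "orientation-dependent; evaluated on canonical (min,max) margins")
_register(37, "Maxwell-Pilliner", "pm1", True, True,
          lambda a, b, c, d: 2 * (a * d - b * c) / ((a + b) * (c + d) + (a + c) * (b + d)))
_register(38, "Harris-Lahey", "zero_p", True, False, _harris_lahey,
          "raw range [0, p]; divided by p")
_register(39, "CT1", "unit", True, False,
          lambda a, b, c, d: np.log(1 + a + d) / np.log(1 + _p(a, b, c, d)),
          "Consonni-Todeschini 1")
_register(40, "CT2", "unit", True, False,
          lambda a, b, c, d: (np.log(1 + _p(a, b, c, d)) - np.log(1 + b + c))
          / np.log(1 + _p(a, b, c, d)),
          "Consonni-Todeschini 2")
_register(41, "CT3", "unit", False, False,
          lambda a, b, c, d: np.log(1 + a) / np.log(1 + _p(a, b, c, d)),
          "Consonni-Todeschini 3; < 1 on identical inputs when d > 0")
_register(42, "CT4", "unit", True, False,
          lambda a, b, c, d: np.log(1 + a) / np.log(1 + a + b + c),
          "Consonni-Todeschini 4")
_register(43, "CT5", "pm1", False, True,
          lambda a, b, c, d: (np.log(1 + a * d) - np.log(1 + b * c))
          / np.log(1 + _p(a, b, c, d) ** 2 / 4.0),
          "Consonni-Todeschini 5")
_register(44, "Austin-Colwell angular coeff.", "unit", True, False,
          lambda a, b, c, d: 2.0 / np.pi * np.arcsin(np.sqrt((a + d) / _p(a, b, c, d))))

SELF_UNIT_BINARY_IDS = tuple(i for i, co in sorted(BINARY_COEFFICIENTS.items()) if co.self_unit)


def binary_similarity(coefficient_id: int, counts: ConfusionCounts) -> float:
    """Evaluate binary coefficient ``coefficient_id`` on confusion counts."""
    try:
        coefficient = BINARY_COEFFICIENTS[coefficient_id]
    except KeyError:
        raise SimilarityError(f"unknown binary coefficient id {coefficient_id}") from None
    if counts.p == 0:
        raise SimilarityError("empty fingerprints (length 0)")
    return float(coefficient.evaluate(counts.a, counts.b, counts.c, counts.d))


# ---------------------------------------------------------------------------
# non-binary coefficient registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NonBinaryCoefficient:
    id: int
    name: str
    code: str
    func: Callable[[np.ndarray, np.ndarray], float]
    source: str = ""

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise SimilarityError(f"vector length mismatch: {x.shape} vs {y.shape}")
        if (x < 0).any() or (y < 0).any():
            raise SimilarityError("non-binary coefficients require nonnegative vectors")
        if np.array_equal(x, y):
            return 1.0
        return float(np.clip(self.func(x, y), 0.0, 1.0))


def _ratio_terms(x, y, f):
    s = x + y
    with np.errstate(divide="ignore", invalid="ignore"):
        t = f(x, y, s)
    return np.where(s == 0, 0.0, t)  # 0/0 components contribute 0


def _mean_canberra(x, y):
    return 1.0 - np.mean(_ratio_terms(x, y, lambda x, y, s: np.abs(x - y) / s))


def _divergence(x, y):
    return 1.0 - np.mean(_ratio_terms(x, y, lambda x, y, s: ((x - y) / s) ** 2))


def _bray_curtis(x, y):
    denom = np.sum(x + y)
    return 1.0 if denom == 0 else 1.0 - np.sum(np.abs(x - y)) / denom


def _nb_dice(x, y):
    denom = np.sum(x * x) + np.sum(y * y)
    return 0.0 if denom == 0 else 2.0 * np.sum(x * y) / denom


def _nb_sokal_sneath(x, y):
    xy = np.sum(x * y)
    denom = 2.0 * np.sum(x * x) + 2.0 * np.sum(y * y) - 3.0 * xy
    return 0.0 if denom == 0 else xy / denom


def _nb_cosine(x, y):
    denom = math.sqrt(np.sum(x * x) * np.sum(y * y))
    return 0.0 if denom == 0 else float(np.sum(x * y)) / denom


_HOLLIDAY = "Holliday et al. 2002 continuous-coefficient roster, entry {}"

NONBINARY_COEFFICIENTS: dict[int, NonBinaryCoefficient] = {
    1: NonBinaryCoefficient(1, "Mean Camberra", "MC", _mean_canberra, _HOLLIDAY.format(1)),
    2: NonBinaryCoefficient(2, "Divergence", "Div", _divergence, _HOLLIDAY.format(2)),
    3: NonBinaryCoefficient(3, "Bray/Curtis", "BC", _bray_curtis, _HOLLIDAY.format(3)),
    4: NonBinaryCoefficient(4, "Dice", "Dice", _nb_dice, _HOLLIDAY.format(4)),
    5: NonBinaryCoefficient(5, "Sokal/Sneath", "SS1", _nb_sokal_sneath, _HOLLIDAY.format(5)),
    6: NonBinaryCoefficient(6, "Cosine/Ochiai", "Cos", _nb_cosine, _HOLLIDAY.format(6)),
}


def nonbinary_similarity(coefficient_id: int, x, y) -> float:
    try:
        coefficient = NONBINARY_COEFFICIENTS[coefficient_id]
    except KeyError:
        raise SimilarityError(f"unknown non-binary coefficient id {coefficient_id}") from None
    return coefficient.evaluate(np.asarray(x, dtype=float), np.asarray(y, dtype=float))


# ---------------------------------------------------------------------------
# weights, config, combined index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityWeights:
    w_fp: float
    w_cd: float
    w_hd: float
    w_fg: float

    def __post_init__(self) -> None:
        weights = (self.w_fp, self.w_cd, self.w_hd, self.w_fg)
        if any(w < -WEIGHT_TOLERANCE or w > 1 + WEIGHT_TOLERANCE for w in weights):
            raise SimilarityError(f"weights must lie in [0, 1], got {weights}")
        if abs(sum(weights) - 1.0) > WEIGHT_TOLERANCE:
            raise SimilarityError(f"weights must sum to 1, got {sum(weights)!r}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_fp, self.w_cd, self.w_hd, self.w_fg)


@dataclass(frozen=True)
class SimilarityConfig:
    fingerprint: str = "extended"
    binary_id: int = 37
    nonbinary_id: int = 3
    weights: SimilarityWeights = field(
        default_factory=lambda: SimilarityWeights(0.4, 0.35, 0.1, 0.15)
    )
    mode: str = "geometric"
    # per-dataset min-max scaling of the CD/HD/FG vectors before comparison;
    # off by default (raw vectors are the primary convention)
    scale_descriptors: bool = False

    def __post_init__(self) -> None:
        if self.binary_id not in BINARY_COEFFICIENTS:
            raise SimilarityError(f"unknown binary coefficient id {self.binary_id}")
        if self.nonbinary_id not in NONBINARY_COEFFICIENTS:
            raise SimilarityError(f"unknown non-binary coefficient id {self.nonbinary_id}")
        if self.mode not in ("geometric", "arithmetic"):
            raise SimilarityError(f"mode must be 'geometric' or 'arithmetic', got {self.mode!r}")


def default_config() -> SimilarityConfig:
    """The shipped default: extended fingerprint, Maxwell-Pilliner (37),
    Bray-Curtis (3), weights (fp, cd, hd, fg) = (0.4, 0.35, 0.1, 0.15)."""
    return SimilarityConfig()


def load_config(path: str | Path) -> SimilarityConfig:
    """Load a YAML config: fingerprint, binary_coefficient,
    nonbinary_coefficient, weights {fp, cd, hd, fg}, mode."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    weights = data.get("weights", {})
    base = default_config()
    return SimilarityConfig(
        fingerprint=data.get("fingerprint", base.fingerprint),
        binary_id=int(data.get("binary_coefficient", base.binary_id)),
        nonbinary_id=int(data.get("nonbinary_coefficient", base.nonbinary_id)),
        weights=SimilarityWeights(
            w_fp=float(weights.get("fp", base.weights.w_fp)),
            w_cd=float(weights.get("cd", base.weights.w_cd)),
            w_hd=float(weights.get("hd", base.weights.w_hd)),
            w_fg=float(weights.get("fg", base.weights.w_fg)),
        ),
        mode=data.get("mode", base.mode),
        scale_descriptors=bool(data.get("scale_descriptors", base.scale_descriptors)),
    )


@dataclass(frozen=True)
class MoleculeKeys:
    """All four keys of one molecule under one fingerprint type."""

    fingerprint: BitFingerprint
    cd: np.ndarray
    hd: np.ndarray
    fg: np.ndarray


def compute_keys(molecule: Molecule, fingerprint_type: str = "extended") -> MoleculeKeys:
    return MoleculeKeys(
        fingerprint=compute_fingerprint(molecule, fingerprint_type),
        cd=compute_cd(molecule).as_vector(),
        hd=compute_hd(molecule).as_vector(),
        fg=compute_fg(molecule).as_vector(),
    )


def minmax_scale_matrix(matrix: np.ndarray) -> np.ndarray:
    """Column-wise min-max scaling to [0, 1]; zero-spread columns map to 0."""
    matrix = np.asarray(matrix, dtype=float)
    lo = matrix.min(axis=0)
    spread = matrix.max(axis=0) - lo
    spread = np.where(spread == 0, 1.0, spread)
    return (matrix - lo) / spread


def scale_molecule_keys(keys: Sequence[MoleculeKeys]) -> list[MoleculeKeys]:
    """Apply per-dataset min-max scaling to the descriptor vectors of a set
    of molecule keys (fingerprints are untouched)."""
    scaled = {
        name: minmax_scale_matrix(np.array([getattr(k, name) for k in keys]))
        for name in ("cd", "hd", "fg")
    }
    return [
        MoleculeKeys(
            fingerprint=k.fingerprint,
            cd=scaled["cd"][i],
            hd=scaled["hd"][i],
            fg=scaled["fg"][i],
        )
        for i, k in enumerate(keys)
    ]


def component_similarities(
    keys_a: MoleculeKeys, keys_b: MoleculeKeys, config: SimilarityConfig
) -> tuple[float, float, float, float]:
    s_fp = binary_similarity(config.binary_id, confusion_counts(keys_a.fingerprint, keys_b.fingerprint))
    s_cd = nonbinary_similarity(config.nonbinary_id, keys_a.cd, keys_b.cd)
    s_hd = nonbinary_similarity(config.nonbinary_id, keys_a.hd, keys_b.hd)
    s_fg = nonbinary_similarity(config.nonbinary_id, keys_a.fg, keys_b.fg)
    return s_fp, s_cd, s_hd, s_fg


def combine_components(components: Sequence[float], weights: SimilarityWeights, mode: str) -> float:
    """Fold the four component similarities into the SI.

    Geometric mode: product of s_k^w_k with the convention that a factor with
    weight 0 contributes 1 (0^0 = 1). Arithmetic mode: sum of w_k * s_k.
    """
    w = weights.as_tuple()
    if mode == "arithmetic":
        return float(sum(wk * sk for wk, sk in zip(w, components)))
    si = 1.0
    for wk, sk in zip(w, components):
        if wk == 0.0:
            continue
        si *= sk ** wk
    return float(si)


def combined_similarity(
    keys_a: MoleculeKeys, keys_b: MoleculeKeys, config: SimilarityConfig | None = None
) -> float:
    """The similarity index SI(A, B) in [0, 1]."""
    config = config or default_config()
    return combine_components(
        component_similarities(keys_a, keys_b, config), config.weights, config.mode
    )


def pairwise_similarity_rows(
    molecules: Sequence[Molecule], config: SimilarityConfig | None = None
) -> list[dict]:
    """All-pairs component and combined similarities, one dict per (i < j)
    pair with keys id_a, id_b, s_fp, s_cd, s_hd, s_fg, si."""
    config = config or default_config()
    keys = [compute_keys(m, config.fingerprint) for m in molecules]
    rows = []
    for i in range(len(molecules)):
        for j in range(i + 1, len(molecules)):
            s_fp, s_cd, s_hd, s_fg = component_similarities(keys[i], keys[j], config)
            rows.append(
                {
                    "id_a": molecules[i].id,
                    "id_b": molecules[j].id,
                    "s_fp": s_fp,
                    "s_cd": s_cd,
                    "s_hd": s_hd,
                    "s_fg": s_fg,
                    "si": combine_components((s_fp, s_cd, s_hd, s_fg), config.weights, config.mode),
                }
            )
    return rows


def config_with_weights(config: SimilarityConfig, weights: SimilarityWeights) -> SimilarityConfig:
    return replace(config, weights=weights)
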