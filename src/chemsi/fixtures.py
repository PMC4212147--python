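"""Packaged test data: a curated SMILES library and a seeded synthetic
property generator.

The library holds 60 small organics arranged as 15 homologous clusters of 4
(isomers plus adjacent chain homologues): alkanes, alcohols, diols, amines,
diamines, alkyl halides (Cl/Br/I), halobenzenes, benzenes, phenols, ketones,
sulfides/thiols, organophosphorus and organoboron esters. Read-across is
only meaningful inside an applicability domain, so the clustering guarantees
that every compound keeps close structural neighbours even after the seeded
sub-sampling; jointly the clusters cover every hetero-atom the HD key counts
(N, O, P, S, F, Cl, Br, I, B). Several member pairs differ only in the
multiplicity of one functional group (butanol/butanediol, toluene/xylene,
butanone/acetylacetone, ...), which is exactly the occurrence-count signal
the FG key adds over boolean fingerprints.

Synthetic endpoint values are a stated linear function of constitutional
descriptors plus Gaussian noise, by design: the property is driven by
information the similarity index itself sees, so read-across recovery on
these fixtures is a meaningful end-to-end sanity check (high LOO R^2
expected) - not a claim about real endpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from chemsi.chemio import Molecule, PropertyDataset, parse_structure, write_dataset
from chemsi.descriptor_keys import CD_FIELDS, compute_cd

# (id, SMILES): curated library; order is part of the fixture contract.
SMILES_LIBRARY: tuple[tuple[str, str], ...] = (
    # cluster 1: C6 alkane isomers
    ("hexane", "CCCCCC"),
    ("2-methylpentane", "CCCC(C)C"),
    ("3-methylpentane", "CCC(C)CC"),
    ("2,2-dimethylbutane", "CCC(C)(C)C"),
    # cluster 2: C4 alcohol isomers
    ("butan-1-ol", "CCCCO"),
    ("butan-2-ol", "CCC(C)O"),
    ("2-methylpropan-1-ol", "CC(C)CO"),
    ("2-methylpropan-2-ol", "CC(C)(C)O"),
    # cluster 3: C4 diol isomers (hydroxyl-doubling partners of cluster 2)
    ("butane-1,4-diol", "OCCCCO"),
    ("butane-1,3-diol", "CC(O)CCO"),
    ("butane-2,3-diol", "CC(O)C(C)O"),
    ("butane-1,2-diol", "CCC(O)CO"),
    # cluster 4: C4 amine isomers
    ("butylamine", "CCCCN"),
    ("sec-butylamine", "CCC(C)N"),
    ("isobutylamine", "CC(C)CN"),
    ("tert-butylamine", "CC(C)(C)N"),
    # cluster 5: C4 diamine isomers (amine-doubling partners of cluster 4)
    ("butane-1,4-diamine", "NCCCCN"),
    ("butane-1,3-diamine", "CC(N)CCN"),
    ("butane-1,2-diamine", "CCC(N)CN"),
    ("2-methylpropane-1,2-diamine", "CC(C)(N)CN"),
    # cluster 6: C4 chloride isomers
    ("1-chlorobutane", "CCCCCl"),
    ("2-chlorobutane", "CCC(C)Cl"),
    ("isobutyl-chloride", "CC(C)CCl"),
    ("tert-butyl-chloride", "CC(C)(C)Cl"),
    # cluster 7: C4 bromide isomers
    ("1-bromobutane", "CCCCBr"),
    ("2-bromobutane", "CCC(C)Br"),
    ("isobutyl-bromide", "CC(C)CBr"),
    ("tert-butyl-bromide", "CC(C)(C)Br"),
    # cluster 8: C4/C5 iodides (five members: the endpoint extreme needs the
    # most sampling resilience)
    ("1-iodobutane", "CCCCI"),
    ("2-iodobutane", "CCC(C)I"),
    ("isobutyl-iodide", "CC(C)CI"),
    ("tert-butyl-iodide", "CC(C)(C)I"),
    ("neopentyl-iodide", "CC(C)(C)CI"),
    # cluster 9: halobenzenes (near-equal endpoint by construction)
    ("fluorobenzene", "Fc1ccccc1"),
    ("1,2-dichlorobenzene", "Clc1ccccc1Cl"),
    ("1,4-dichlorobenzene", "Clc1ccc(Cl)cc1"),
    # cluster 10: methylbenzenes (toluene/xylene methyl doubling)
    ("toluene", "Cc1ccccc1"),
    ("o-xylene", "Cc1ccccc1C"),
    ("m-xylene", "Cc1cccc(C)c1"),
    ("p-xylene", "Cc1ccc(C)cc1"),
    # cluster 11: methylphenols (cresol/xylenol methyl doubling)
    ("o-cresol", "Cc1ccccc1O"),
    ("m-cresol", "Cc1cccc(O)c1"),
    ("p-cresol", "Cc1ccc(O)cc1"),
    ("2,4-dimethylphenol", "Cc1ccc(O)c(C)c1"),
    # cluster 12: C5/C6 ketones
    ("pentan-2-one", "CCCC(C)=O"),
    ("pentan-3-one", "CCC(=O)CC"),
    ("3-methylbutan-2-one", "CC(C)C(C)=O"),
    ("hexan-2-one", "CCCCC(C)=O"),
    # cluster 13: C4H10S thiol/sulfide isomers
    ("diethyl-sulfide", "CCSCC"),
    ("methyl-propyl-sulfide", "CCCSC"),
    ("isopropyl-methyl-sulfide", "CC(C)SC"),
    ("butane-1-thiol", "CCCCS"),
    # cluster 14: organophosphorus esters
    ("trimethyl-phosphite", "COP(OC)OC"),
    ("dimethyl-methylphosphonate", "CP(=O)(OC)OC"),
    ("dimethyl-ethylphosphonate", "CCP(=O)(OC)OC"),
    ("triethyl-phosphate", "CCOP(=O)(OCC)OCC"),
    # cluster 15: alkylboronic acids
    ("propylboronic-acid", "CCCB(O)O"),
    ("isopropylboronic-acid", "CC(C)B(O)O"),
    ("butylboronic-acid", "CCCCB(O)O"),
    ("sec-butylboronic-acid", "CCC(C)B(O)O"),
)


class FixtureError(ValueError):
    """Raised for unsatisfiable fixture specifications."""


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic synthetic-dataset recipe.

    ``coefficients`` maps constitutional-descriptor names to linear weights;
    the endpoint is y = sum(beta_f * CD_f) + N(0, sigma^2) with an rng seeded
    by ``seed``. Same spec + seed -> byte-identical dataset file.
    """

    n_molecules: int = 50
    coefficients: tuple[tuple[str, float], ...] = (("MW", 0.01), ("nHet", -0.5))
    sigma: float = 0.1
    seed: int = 42
    endpoint_name: str = "synthetic"

    def __post_init__(self) -> None:
        for name, _beta in self.coefficients:
            if name not in CD_FIELDS:
                raise FixtureError(f"unknown constitutional descriptor {name!r}")
        if self.sigma < 0:
            raise FixtureError("noise sd must be nonnegative")


def library_molecules(n: int | None = None) -> list[Molecule]:
    pairs = SMILES_LIBRARY if n is None else SMILES_LIBRARY[:n]
    return [parse_structure(smi, record_id=cid) for cid, smi in pairs]


def build_fixture(
    spec: FixtureSpec | None = None,
    library: tuple[tuple[str, str], ...] = SMILES_LIBRARY,
) -> PropertyDataset:
    """Sample ``n_molecules`` library compounds (seeded, without replacement)
    and attach synthetic property values."""
    spec = spec or FixtureSpec()
    if spec.n_molecules > len(library):
        raise FixtureError(
            f"requested {spec.n_molecules} molecules but the library has {len(library)}"
        )
    rng = np.random.default_rng(spec.seed)
    chosen = sorted(rng.choice(len(library), size=spec.n_molecules, replace=False))
    records = []
    for index in chosen:
        cid, smiles = library[index]
        molecule = parse_structure(smiles, record_id=cid)
        cd = compute_cd(molecule)
        signal = sum(beta * getattr(cd, name) for name, beta in spec.coefficients)
        noise = rng.normal(0.0, spec.sigma) if spec.sigma > 0 else 0.0
        records.append((cid, molecule, float(signal + noise)))
    return PropertyDataset(records=records, endpoint_name=spec.endpoint_name)


def write_fixture(
    spec: FixtureSpec, dataset_path: str | Path, metadata_path: str | Path | None = None
) -> PropertyDataset:
    """Write the dataset CSV plus a sidecar JSON recording beta, sigma, seed."""
    dataset = build_fixture(spec)
    write_dataset(dataset, dataset_path)
    if metadata_path is None:
        metadata_path = Path(dataset_path).with_suffix(".meta.json")
    Path(metadata_path).write_text(
        json.dumps(
            {
                "n_molecules": spec.n_molecules,
                "coefficients": dict(spec.coefficients),
                "sigma": spec.sigma,
                "seed": spec.seed,
                "endpoint_name": spec.endpoint_name,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return dataset
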