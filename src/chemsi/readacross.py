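"""Read-across prediction: SI-weighted mean of the k most similar compounds.

A query's endpoint is predicted as sum(SI_i * y_i) / sum(SI_i) over its k=3
nearest training neighbours under the similarity index; leave-one-out (LOO)
cross-validation over a dataset yields R^2 (coefficient of determination,
1 - SSres/SStot) and RMSE. Ties in SI are broken by ascending compound id so
repeated runs are identical; if all k neighbour similarities are zero the
prediction falls back to the unweighted mean and is flagged low-confidence.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from chemsi.chemio import Molecule, PropertyDataset
from chemsi.similarity import (
    MoleculeKeys,
    SimilarityConfig,
    combined_similarity,
    compute_keys,
    default_config,
)


class ReadAcrossError(ValueError):
    """Raised for invalid read-across inputs (e.g. too few training compounds)."""


@dataclass(frozen=True)
class Neighbor:
    id: str
    si: float
    value: float


@dataclass(frozen=True)
class Prediction:
    query_id: str
    neighbors: tuple[Neighbor, ...]  # sorted by SI descending
    value: float
    low_confidence: bool = False


@dataclass(frozen=True)
class RunMetrics:
    """LOO quality metrics. ``r2`` is 1 - SSres/SStot; ``pearson_r2`` (the
    squared correlation reading of "R^2") is carried alongside in reports.
    ``degenerate_variance`` marks a constant-value dataset (SStot = 0), for
    which r2 is reported as 1."""

    r2: float
    rmse: float
    n: int
    pearson_r2: float = float("nan")
    degenerate_variance: bool = False


def _select_neighbors(
    similarities: Sequence[float],
    ids: Sequence[str],
    values: Sequence[float],
    k: int,
) -> tuple[Neighbor, ...]:
    order = sorted(range(len(ids)), key=lambda i: (-similarities[i], ids[i]))
    return tuple(Neighbor(ids[i], float(similarities[i]), float(values[i])) for i in order[:k])


def _weighted_prediction(neighbors: tuple[Neighbor, ...]) -> tuple[float, bool]:
    total_si = sum(n.si for n in neighbors)
    if total_si == 0.0:
        return sum(n.value for n in neighbors) / len(neighbors), True
    return sum(n.si * n.value for n in neighbors) / total_si, False


def predict(
    query: Molecule,
    training: PropertyDataset,
    config: SimilarityConfig | None = None,
    k: int = 3,
    query_keys: MoleculeKeys | None = None,
    training_keys: Sequence[MoleculeKeys] | None = None,
) -> Prediction:
    """Predict the endpoint of ``query`` from its k nearest training compounds.

    ``query_keys``/``training_keys`` allow callers (LOO, grids) to reuse
    precomputed keys; results are identical with or without them.
    """
    config = config or default_config()
    if config.scale_descriptors and query_keys is None and training_keys is None:
        from chemsi.similarity import scale_molecule_keys

        joint = [compute_keys(query, config.fingerprint)] + [
            compute_keys(m, config.fingerprint) for m in training.molecules
        ]
        joint = scale_molecule_keys(joint)
        query_keys, training_keys = joint[0], joint[1:]
    return _predict_core(
        query.id,
        query_keys if query_keys is not None else compute_keys(query, config.fingerprint),
        training.ids,
        training.molecules,
        training.values,
        config,
        k,
        training_keys,
    )


def _predict_core(
    query_id: str,
    query_keys: MoleculeKeys,
    ids: Sequence[str],
    molecules: Sequence[Molecule],
    values: Sequence[float],
    config: SimilarityConfig,
    k: int,
    training_keys: Sequence[MoleculeKeys] | None,
) -> Prediction:
    if len(ids) < k:
        raise ReadAcrossError(f"need at least k={k} training compounds, got {len(ids)}")
    if training_keys is None:
        training_keys = [compute_keys(m, config.fingerprint) for m in molecules]
    similarities = [combined_similarity(query_keys, tk, config) for tk in training_keys]
    neighbors = _select_neighbors(similarities, ids, values, k)
    value, low_confidence = _weighted_prediction(neighbors)
    return Prediction(query_id, neighbors, value, low_confidence)


def metrics_from_predictions(
    observed: Sequence[float], predicted: Sequence[float]
) -> RunMetrics:
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    residual = y - yhat
    ss_res = float(np.sum(residual**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmse = math.sqrt(ss_res / len(y))
    if ss_tot == 0.0:
        return RunMetrics(r2=1.0, rmse=rmse, n=len(y), degenerate_variance=True)
    if np.std(yhat) == 0.0:
        pearson_r2 = float("nan")
    else:
        pearson_r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    return RunMetrics(r2=1.0 - ss_res / ss_tot, rmse=rmse, n=len(y), pearson_r2=pearson_r2)


def loo_predictions(
    data: PropertyDataset,
    config: SimilarityConfig | None = None,
    k: int = 3,
    cache_keys: bool = True,
) -> list[Prediction]:
    """Leave-one-out predictions for every compound.

    With ``cache_keys`` (default) all fingerprints and descriptor keys are
    computed once and shared across folds; disabling the cache recomputes
    them per fold and must give identical results.
    """
    config = config or default_config()
    if len(data) < k + 1:
        raise ReadAcrossError(f"LOO needs at least k+1={k + 1} compounds, got {len(data)}")
    ids, molecules, values = data.ids, data.molecules, data.values
    if cache_keys or config.scale_descriptors:
        # descriptor scaling is per-dataset, so it always needs the full key set
        all_keys: list[MoleculeKeys] | None = [
            compute_keys(m, config.fingerprint) for m in molecules
        ]
        if config.scale_descriptors:
            from chemsi.similarity import scale_molecule_keys

            all_keys = scale_molecule_keys(all_keys)
    else:
        all_keys = None

    predictions: list[Prediction] = []
    failures: list[tuple[str, str]] = []
    for i, molecule in enumerate(molecules):
        rest = [j for j in range(len(molecules)) if j != i]
        try:
            predictions.append(
                _predict_core(
                    ids[i],
                    all_keys[i] if all_keys is not None else compute_keys(molecule, config.fingerprint),
                    [ids[j] for j in rest],
                    [molecules[j] for j in rest],
                    [values[j] for j in rest],
                    config,
                    k,
                    None if all_keys is None else [all_keys[j] for j in rest],
                )
            )
        except Exception as exc:  # per-compound failures are collected
            failures.append((ids[i], str(exc)))
    if failures:
        if len(failures) > 0.05 * len(molecules):
            detail = "; ".join(f"{cid}: {msg}" for cid, msg in failures[:5])
            raise ReadAcrossError(
                f"{len(failures)}/{len(molecules)} compounds failed LOO: {detail}"
            )
    return predictions


def loo_validate(
    data: PropertyDataset,
    config: SimilarityConfig | None = None,
    k: int = 3,
    cache_keys: bool = True,
) -> RunMetrics:
    """LOO cross-validation metrics (R^2, RMSE) for one dataset and config."""
    predictions = loo_predictions(data, config, k=k, cache_keys=cache_keys)
    observed = {cid: value for cid, _m, value in data.records}
    return metrics_from_predictions(
        [observed[p.query_id] for p in predictions], [p.value for p in predictions]
    )


def write_predictions_csv(
    predictions: Sequence[Prediction], data: PropertyDataset, path: str | Path, k: int = 3
) -> None:
    """Per-compound prediction dump: id, observed, predicted, neighbour ids/SIs."""
    observed = {cid: value for cid, _m, value in data.records}
    header = ["id", "observed", "predicted"]
    for rank in range(1, k + 1):
        header += [f"n{rank}_id", f"n{rank}_si"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for p in predictions:
            row = [p.query_id, repr(observed[p.query_id]), repr(p.value)]
            for rank in range(k):
                if rank < len(p.neighbors):
                    row += [p.neighbors[rank].id, repr(p.neighbors[rank].si)]
                else:
                    row += ["", ""]
            writer.writerow(row)


def read_predictions_csv(path: str | Path) -> tuple[list[float], list[float]]:
    """Observed/predicted columns back from a prediction dump (for metric
    round-trip checks)."""
    observed, predicted = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            observed.append(float(row["observed"]))
            predicted.append(float(row["predicted"]))
    return observed, predicted
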