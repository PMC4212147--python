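"""Two-stage combinatorial benchmarking of similarity-index configurations.

Stage 1 sweeps fingerprint family x binary coefficient with fingerprint-only
weights (1, 0, 0, 0) - a pure fingerprint benchmark. Stage 2 fixes the
winning (fingerprint, binary coefficient) pair and sweeps weight schemes
(a constrained 0.05/0.1 lattice summing to 1) x non-binary coefficient.

Every run is scored by leave-one-out read-across on each supplied dataset;
batches are ranked by a desirability score DES (geometric mean of the
min-max-scaled quality parameters, RMSEs complemented) and a utility score
UTI (the arithmetic mean of the same parameters). With two datasets this is

    DES = p1^0.25 * p2^0.25 * p3^0.25 * p4^0.25
    UTI = 0.25*p1 + 0.25*p2 + 0.25*p3 + 0.25*p4

where (p1..p4) are scaled R^2 and complemented scaled RMSE per dataset.
Scaling is per-batch (across the runs being ranked); a metric with zero
spread across the batch is set to 1 for every run, with a warning.

The grid engine evaluates coefficients on precomputed pairwise confusion
counts and key matrices, which makes the full 9 x 44 stage-1 sweep cheap;
its LOO path uses the same neighbour-selection and metric code as
:mod:`chemsi.readacross`.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

from chemsi.chemio import PropertyDataset
from chemsi.descriptor_keys import compute_cd, compute_fg, compute_hd
from chemsi.fingerprints import compute_fingerprint, list_available_types
from chemsi.readacross import RunMetrics, _select_neighbors, _weighted_prediction, metrics_from_predictions
from chemsi.similarity import (
    BINARY_COEFFICIENTS,
    NONBINARY_COEFFICIENTS,
    SimilarityConfig,
    SimilarityError,
    SimilarityWeights,
)

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """Raised for unusable grids or batches."""


# ---------------------------------------------------------------------------
# weight lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightGrid:
    """Ranges and steps of the stage-2 weight sweep."""

    fp_range: tuple[float, float] = (0.3, 1.0)
    fp_step: float = 0.1
    cd_range: tuple[float, float] = (0.0, 0.4)
    cd_step: float = 0.05
    hd_range: tuple[float, float] = (0.0, 1.0)
    hd_step: float = 0.05
    fg_range: tuple[float, float] = (0.0, 1.0)
    fg_step: float = 0.05


def _axis(lo: float, hi: float, step: float, name: str) -> list[Fraction]:
    lo_f, hi_f, step_f = (Fraction(x).limit_denominator(10**6) for x in (lo, hi, step))
    if step_f <= 0 or (hi_f - lo_f) % step_f != 0:
        raise EvaluationError(f"{name}: step {step} does not divide range [{lo}, {hi}]")
    n = int((hi_f - lo_f) / step_f)
    return [lo_f + i * step_f for i in range(n + 1)]


def enumerate_weights(grid: WeightGrid | None = None) -> list[SimilarityWeights]:
    """Exhaustive lattice enumeration of weight tuples with sum exactly 1.

    Order is deterministic and lexicographic in (w_fp, w_cd, w_hd); w_fg is
    determined by the sum constraint and kept only if it lies on its own
    step lattice inside its range.
    """
    grid = grid or WeightGrid()
    fp_axis = _axis(*grid.fp_range, grid.fp_step, "w_fp")
    cd_axis = _axis(*grid.cd_range, grid.cd_step, "w_cd")
    hd_axis = _axis(*grid.hd_range, grid.hd_step, "w_hd")
    fg_lo, fg_hi, fg_step = (
        Fraction(grid.fg_range[0]).limit_denominator(10**6),
        Fraction(grid.fg_range[1]).limit_denominator(10**6),
        Fraction(grid.fg_step).limit_denominator(10**6),
    )
    weights: list[SimilarityWeights] = []
    for w_fp in fp_axis:
        for w_cd in cd_axis:
            for w_hd in hd_axis:
                w_fg = 1 - w_fp - w_cd - w_hd
                if w_fg < fg_lo or w_fg > fg_hi or (w_fg - fg_lo) % fg_step != 0:
                    continue
                weights.append(
                    SimilarityWeights(float(w_fp), float(w_cd), float(w_hd), float(w_fg))
                )
    return weights


# ---------------------------------------------------------------------------
# run results
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    config: SimilarityConfig
    metrics: dict[str, RunMetrics]  # per dataset (endpoint name -> metrics)
    scaled_params: tuple[float, ...] = ()
    des: float = float("nan")
    uti: float = float("nan")
    rank_des: int = 0
    rank_uti: int = 0


# ---------------------------------------------------------------------------
# vectorized dataset state
# ---------------------------------------------------------------------------

@dataclass
class _DatasetState:
    """Precomputed per-dataset matrices used by the grid engine."""

    name: str
    ids: list[str]
    values: list[float]
    cd: np.ndarray  # (n, 35)
    hd: np.ndarray  # (n, 11)
    fg: np.ndarray  # (n, 154)
    bit_matrices: dict[str, np.ndarray] = field(default_factory=dict)  # fp type -> (n, L) bool
    counts: dict[str, tuple[np.ndarray, ...]] = field(default_factory=dict)
    nonbinary: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_dataset(cls, data: PropertyDataset) -> "_DatasetState":
        molecules = data.molecules
        return cls(
            name=data.endpoint_name,
            ids=list(data.ids),
            values=list(data.values),
            cd=np.array([compute_cd(m).as_vector() for m in molecules]),
            hd=np.array([compute_hd(m).as_vector() for m in molecules]),
            fg=np.array([compute_fg(m).as_vector() for m in molecules]),
        )

    def _bits(self, data: PropertyDataset, fp_type: str) -> np.ndarray:
        if fp_type not in self.bit_matrices:
            fps = [compute_fingerprint(m, fp_type) for m in data.molecules]
            length = fps[0].type.length
            mat = np.zeros((len(fps), length), dtype=bool)
            for i, fp in enumerate(fps):
                mat[i, list(fp.set_bits)] = True
            self.bit_matrices[fp_type] = mat
        return self.bit_matrices[fp_type]

    def confusion(self, data: PropertyDataset, fp_type: str) -> tuple[np.ndarray, ...]:
        if fp_type not in self.counts:
            mat = self._bits(data, fp_type)
            a = (mat.astype(np.int64) @ mat.T.astype(np.int64)).astype(float)
            n_bits = mat.sum(axis=1).astype(float)
            b = n_bits[:, None] - a
            c = n_bits[None, :] - a
            d = mat.shape[1] - a - b - c
            self.counts[fp_type] = (a, b, c, d)
        return self.counts[fp_type]

    def nonbinary_matrix(self, coefficient_id: int, key: str, scaled: bool = False) -> np.ndarray:
        cache_key = (coefficient_id, key, scaled)
        if cache_key not in self.nonbinary:
            matrix = getattr(self, key)
            if scaled:
                from chemsi.similarity import minmax_scale_matrix

                matrix = minmax_scale_matrix(matrix)
            self.nonbinary[cache_key] = _pairwise_nonbinary(coefficient_id, matrix)
        return self.nonbinary[cache_key]


def _pairwise_nonbinary(coefficient_id: int, m: np.ndarray) -> np.ndarray:
    """All-pairs non-binary similarity matrix; same conventions as the scalar
    registry (identical rows -> 1, 0/0 component terms -> 0)."""
    x = m[:, None, :]
    y = m[None, :, :]
    code = NONBINARY_COEFFICIENTS[coefficient_id].code
    with np.errstate(divide="ignore", invalid="ignore"):
        if code in ("MC", "Div"):
            s = x + y
            t = np.abs(x - y) / s if code == "MC" else ((x - y) / s) ** 2
            t = np.where(s == 0, 0.0, t)
            out = 1.0 - t.mean(axis=2)
        elif code == "BC":
            denom = (x + y).sum(axis=2)
            out = np.where(denom == 0, 1.0, 1.0 - np.abs(x - y).sum(axis=2) / denom)
        else:
            gram = m @ m.T
            sq = np.diag(gram).copy()
            if code == "Dice":
                denom = sq[:, None] + sq[None, :]
                out = np.where(denom == 0, 0.0, 2.0 * gram / denom)
            elif code == "SS1":
                denom = 2.0 * sq[:, None] + 2.0 * sq[None, :] - 3.0 * gram
                out = np.where(denom == 0, 0.0, gram / denom)
            elif code == "Cos":
                denom = np.sqrt(sq[:, None] * sq[None, :])
                out = np.where(denom == 0, 0.0, gram / denom)
            else:  # pragma: no cover
                raise SimilarityError(f"unknown non-binary code {code}")
    identical = (m[:, None, :] == m[None, :, :]).all(axis=2)
    out = np.where(identical, 1.0, out)
    return np.clip(np.nan_to_num(out, nan=0.0), 0.0, 1.0)


def _si_matrix(
    state: _DatasetState,
    data: PropertyDataset,
    config: SimilarityConfig,
) -> np.ndarray:
    a, b, c, d = state.confusion(data, config.fingerprint)
    s_fp = BINARY_COEFFICIENTS[config.binary_id].evaluate(a, b, c, d)
    components = [s_fp]
    for key in ("cd", "hd", "fg"):
        components.append(
            state.nonbinary_matrix(config.nonbinary_id, key, config.scale_descriptors)
        )
    w = config.weights.as_tuple()
    if config.mode == "arithmetic":
        return sum(wk * s for wk, s in zip(w, components))
    si = np.ones_like(s_fp)
    for wk, s in zip(w, components):
        if wk == 0.0:
            continue
        si = si * np.power(s, wk)
    return si


def _loo_metrics_from_si(si: np.ndarray, ids: Sequence[str], values: Sequence[float], k: int = 3) -> RunMetrics:
    """LOO metrics from a full SI matrix; shares neighbour selection and
    metric code with :mod:`chemsi.readacross`."""
    predicted = []
    n = len(ids)
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        neighbors = _select_neighbors(
            [float(si[i, j]) for j in rest],
            [ids[j] for j in rest],
            [values[j] for j in rest],
            k,
        )
        predicted.append(_weighted_prediction(neighbors)[0])
    return metrics_from_predictions(values, predicted)


# ---------------------------------------------------------------------------
# grid stages
# ---------------------------------------------------------------------------

def _run_configs(
    datasets: Sequence[PropertyDataset], configs: Sequence[SimilarityConfig], k: int = 3
) -> list[RunResult]:
    if not datasets:
        raise EvaluationError("at least one dataset is required")
    if not configs:
        raise EvaluationError("empty configuration grid; nothing to run")
    names = [d.endpoint_name for d in datasets]
    if len(set(names)) != len(names):
        names = [f"{name}#{i}" for i, name in enumerate(names)]
    states = [_DatasetState.from_dataset(d) for d in datasets]
    results: list[RunResult] = []
    for config in configs:
        try:
            metrics = {}
            for name, state, data in zip(names, states, datasets):
                si = _si_matrix(state, data, config)
                metrics[name] = _loo_metrics_from_si(si, state.ids, state.values, k=k)
            results.append(RunResult(config=config, metrics=metrics))
        except Exception as exc:
            logger.warning("run failed and is excluded from ranking: %s (%s)", config, exc)
    return results


def stage1_grid(
    datasets: Sequence[PropertyDataset],
    fp_types: Sequence[str] | None = None,
    binary_ids: Sequence[int] | None = None,
    k: int = 3,
    rank: bool = True,
) -> list[RunResult]:
    """Fingerprint x binary-coefficient sweep at weights (1, 0, 0, 0)."""
    if fp_types is None:
        fp_types = [t.name for t in list_available_types()]
    if binary_ids is None:
        binary_ids = sorted(BINARY_COEFFICIENTS)
    configs = [
        SimilarityConfig(
            fingerprint=fp,
            binary_id=bid,
            nonbinary_id=3,
            weights=SimilarityWeights(1.0, 0.0, 0.0, 0.0),
        )
        for fp in fp_types
        for bid in binary_ids
    ]
    results = _run_configs(datasets, configs, k=k)
    return rank_results(results) if rank and len(results) >= 2 else results


def stage2_grid(
    datasets: Sequence[PropertyDataset],
    fp_type: str = "extended",
    binary_id: int = 37,
    grid: WeightGrid | None = None,
    nonbinary_ids: Sequence[int] | None = None,
    k: int = 3,
    rank: bool = True,
) -> list[RunResult]:
    """Weight-scheme x non-binary-coefficient sweep at a fixed fingerprint
    and binary coefficient (defaults mirror the stage-1 winner: extended, 37)."""
    if nonbinary_ids is None:
        nonbinary_ids = sorted(NONBINARY_COEFFICIENTS)
    weight_tuples = enumerate_weights(grid)
    configs = [
        SimilarityConfig(
            fingerprint=fp_type, binary_id=binary_id, nonbinary_id=nb_id, weights=w
        )
        for w in weight_tuples
        for nb_id in nonbinary_ids
    ]
    results = _run_configs(datasets, configs, k=k)
    return rank_results(results) if rank and len(results) >= 2 else results


# ---------------------------------------------------------------------------
# desirability / utility ranking
# ---------------------------------------------------------------------------

def _minmax_scale(column: np.ndarray, label: str) -> np.ndarray:
    spread = column.max() - column.min()
    if spread == 0:
        warnings.warn(
            f"metric {label!r} has zero spread across the batch; scaled value set to 1",
            stacklevel=3,
        )
        return np.ones_like(column)
    return (column - column.min()) / spread


def rank_results(batch: list[RunResult]) -> list[RunResult]:
    """Scale metrics per batch, score DES/UTI, and attach both rankings.

    For each dataset, R^2 is min-max scaled to [0,1] and RMSE is min-max
    scaled then complemented (1 - scaled), so 1 is best everywhere. DES is
    the geometric mean of the parameters (0 for any zero parameter), UTI the
    arithmetic mean; ranks 1..n are assigned by descending score with ties
    broken by batch order.
    """
    if len(batch) < 2:
        raise EvaluationError("ranking needs at least 2 runs")
    dataset_names = list(batch[0].metrics)
    for run in batch:
        if list(run.metrics) != dataset_names:
            raise EvaluationError("all runs in a batch must cover the same datasets")

    params: list[np.ndarray] = []
    for name in dataset_names:
        r2 = np.array([run.metrics[name].r2 for run in batch])
        rmse = np.array([run.metrics[name].rmse for run in batch])
        if not (np.isfinite(r2).all() and np.isfinite(rmse).all()):
            raise EvaluationError(f"non-finite metrics in batch for dataset {name!r}")
        params.append(_minmax_scale(r2, f"{name}:r2"))
        params.append(1.0 - _minmax_scale(rmse, f"{name}:rmse"))

    matrix = np.column_stack(params)  # (n_runs, 2 * n_datasets)
    m = matrix.shape[1]
    des = np.where((matrix == 0).any(axis=1), 0.0, np.power(matrix.prod(axis=1), 1.0 / m))
    uti = matrix.mean(axis=1)

    order_des = sorted(range(len(batch)), key=lambda i: (-des[i], i))
    order_uti = sorted(range(len(batch)), key=lambda i: (-uti[i], i))
    rank_des = {run_index: rank + 1 for rank, run_index in enumerate(order_des)}
    rank_uti = {run_index: rank + 1 for rank, run_index in enumerate(order_uti)}
    for i, run in enumerate(batch):
        run.scaled_params = tuple(float(v) for v in matrix[i])
        run.des = float(des[i])
        run.uti = float(uti[i])
        run.rank_des = rank_des[i]
        run.rank_uti = rank_uti[i]
    return batch


def agreeing_top_prefix(batch: list[RunResult]) -> int:
    """Length of the leading prefix on which the DES and UTI rankings agree.

    Recorded, not asserted: full agreement at the top of the table is a
    data-dependent property, not a guarantee."""
    by_des = sorted(batch, key=lambda r: r.rank_des)
    by_uti = sorted(batch, key=lambda r: r.rank_uti)
    n = 0
    for x, y in zip(by_des, by_uti):
        if x is not y:
            break
        n += 1
    return n


# ---------------------------------------------------------------------------
# results output
# ---------------------------------------------------------------------------

def write_results_csv(batch: list[RunResult], path: str | Path) -> None:
    """Results table: config columns, raw and
    scaled-complement metrics per dataset, DES, UTI and both ranks. Rows are
    ordered by DES rank; identical inputs give byte-identical files."""
    if not batch:
        raise EvaluationError("no results to write")
    dataset_names = list(batch[0].metrics)
    header = ["fingerprint", "binary_id", "nonbinary_id", "w_fp", "w_cd", "w_hd", "w_fg", "mode"]
    for name in dataset_names:
        header += [f"{name}_r2", f"{name}_rmse", f"{name}_r2_scaled", f"{name}_rmse_complement"]
    header += ["des", "uti", "rank_des", "rank_uti"]
    ordered = sorted(batch, key=lambda r: (r.rank_des if r.rank_des else 0))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for run in ordered:
            cfg = run.config
            row = [
                cfg.fingerprint,
                cfg.binary_id,
                cfg.nonbinary_id,
                repr(cfg.weights.w_fp),
                repr(cfg.weights.w_cd),
                repr(cfg.weights.w_hd),
                repr(cfg.weights.w_fg),
                cfg.mode,
            ]
            for j, name in enumerate(dataset_names):
                metric = run.metrics[name]
                scaled = run.scaled_params[2 * j : 2 * j + 2] if run.scaled_params else ("", "")
                row += [repr(float(metric.r2)), repr(float(metric.rmse))]
                row += [repr(float(s)) if s != "" else "" for s in scaled]
            row += [repr(run.des), repr(run.uti), run.rank_des, run.rank_uti]
            writer.writerow(row)
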