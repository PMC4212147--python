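from fractions import Fraction

import numpy as np
import pytest

from chemsi.evaluation import (
    EvaluationError,
    RunResult,
    WeightGrid,
    _pairwise_nonbinary,
    agreeing_top_prefix,
    enumerate_weights,
    rank_results,
    stage1_grid,
    stage2_grid,
    write_results_csv,
)
from chemsi.readacross import RunMetrics, loo_validate
from chemsi.similarity import (
    SimilarityConfig,
    SimilarityWeights,
    compute_keys,
    nonbinary_similarity,
)


def brute_force_weights(grid: WeightGrid):
    """Independent triple-loop lattice oracle over 0.05-unit integers."""
    def frac(x):
        return Fraction(x).limit_denominator(1000)

    def axis(lo, hi, step):
        lo, hi, step = frac(lo), frac(hi), frac(step)
        values = []
        v = lo
        while v <= hi:
            values.append(v)
            v += step
        return values

    tuples = []
    for fp in axis(*grid.fp_range, grid.fp_step):
        for cd in axis(*grid.cd_range, grid.cd_step):
            for hd in axis(*grid.hd_range, grid.hd_step):
                fg = 1 - fp - cd - hd
                if frac(grid.fg_range[0]) <= fg <= frac(grid.fg_range[1]) and (
                    fg / frac(grid.fg_step)
                ).denominator == 1:
                    tuples.append((float(fp), float(cd), float(hd), float(fg)))
    return tuples


class TestEnumerateWeights:
    def test_fp_fixed_at_one(self):
        grid = WeightGrid(fp_range=(1.0, 1.0))
        assert [w.as_tuple() for w in enumerate_weights(grid)] == [(1.0, 0.0, 0.0, 0.0)]

    def test_fp_fixed_at_point_nine(self):
        grid = WeightGrid(fp_range=(0.9, 0.9))
        assert len(enumerate_weights(grid)) == 6  # cd+hd+fg = 0.1 on the 0.05 lattice

    def test_full_grid_matches_brute_force_oracle(self):
        grid = WeightGrid()
        ours = [w.as_tuple() for w in enumerate_weights(grid)]
        oracle = brute_force_weights(grid)
        assert sorted(ours) == sorted(oracle)
        assert len(ours) == len(set(ours))  # no duplicates

    def test_every_tuple_sums_to_one(self):
        for w in enumerate_weights():
            assert abs(sum(w.as_tuple()) - 1.0) <= 1e-9
            assert 0.3 <= w.w_fp <= 1.0
            assert 0.0 <= w.w_cd <= 0.4

    def test_step_not_dividing_range(self):
        with pytest.raises(EvaluationError, match="does not divide"):
            enumerate_weights(WeightGrid(fp_range=(0.3, 1.0), fp_step=0.15))

    def test_paper_best_weights_in_grid(self):
        assert (0.4, 0.35, 0.1, 0.15) in [w.as_tuple() for w in enumerate_weights()]


class TestGridStages:
    def test_stage1_run_count(self, benchmark_dataset):
        results = stage1_grid(
            [benchmark_dataset], fp_types=["maccs", "estate"], binary_ids=[1, 3, 37]
        )
        assert len(results) == 6

    def test_stage1_single_pair(self, benchmark_dataset):
        results = stage1_grid(
            [benchmark_dataset], fp_types=["estate"], binary_ids=[3], rank=False
        )
        assert len(results) == 1

    def test_duplicate_dataset_gives_identical_per_dataset_metrics(self, benchmark_dataset):
        results = stage1_grid(
            [benchmark_dataset, benchmark_dataset],
            fp_types=["estate"],
            binary_ids=[3, 37],
            rank=False,
        )
        for run in results:
            names = list(run.metrics)
            assert run.metrics[names[0]] == run.metrics[names[1]]

    def test_stage1_matrix_path_matches_readacross(self, benchmark_dataset):
        """The vectorized grid engine and the scalar read-across path agree."""
        config = SimilarityConfig(
            fingerprint="estate",
            binary_id=3,
            weights=SimilarityWeights(1.0, 0.0, 0.0, 0.0),
        )
        results = stage1_grid(
            [benchmark_dataset], fp_types=["estate"], binary_ids=[3], rank=False
        )
        grid_metrics = next(iter(results[0].metrics.values()))
        direct = loo_validate(benchmark_dataset, config)
        assert grid_metrics.r2 == pytest.approx(direct.r2, abs=1e-12)
        assert grid_metrics.rmse == pytest.approx(direct.rmse, abs=1e-12)

    def test_stage2_small_grid(self, benchmark_dataset):
        grid = WeightGrid(fp_range=(1.0, 1.0))
        # the single tuple is (1,0,0,0): all 6 runs tie, so scaling warns
        with pytest.warns(UserWarning, match="zero spread"):
            results = stage2_grid([benchmark_dataset], grid=grid)
        assert len(results) == 6  # 1 weight tuple x 6 non-binary ids
        for run in results:
            assert 0.0 <= run.des <= 1.0
            assert 0.0 <= run.uti <= 1.0

    def test_stage2_matches_scalar_si(self, benchmark_dataset):
        """Vectorized non-binary matrices agree with the scalar registry."""
        molecules = benchmark_dataset.molecules
        keys = [compute_keys(m) for m in molecules]
        cd = np.array([k.cd for k in keys])
        for cid in range(1, 7):
            matrix = _pairwise_nonbinary(cid, cd)
            for i in range(0, len(molecules), 7):
                for j in range(0, len(molecules), 5):
                    assert matrix[i, j] == pytest.approx(
                        nonbinary_similarity(cid, cd[i], cd[j]), abs=1e-12
                    )

    def test_empty_grid_refused(self, benchmark_dataset):
        with pytest.raises(EvaluationError, match="empty configuration grid"):
            stage1_grid([benchmark_dataset], fp_types=[], binary_ids=[])


def _mk_run(metrics_pairs):
    metrics = {
        name: RunMetrics(r2=r2, rmse=rmse, n=10)
        for name, (r2, rmse) in metrics_pairs.items()
    }
    return RunResult(config=SimilarityConfig(), metrics=metrics)


class TestRankResults:
    def test_best_on_all_metrics(self):
        batch = [
            _mk_run({"a": (0.9, 0.1), "b": (0.8, 0.2)}),
            _mk_run({"a": (0.5, 0.5), "b": (0.4, 0.6)}),
            _mk_run({"a": (0.7, 0.3), "b": (0.6, 0.4)}),
        ]
        rank_results(batch)
        assert batch[0].scaled_params == (1.0, 1.0, 1.0, 1.0)
        assert batch[0].des == 1.0 and batch[0].uti == 1.0
        assert batch[0].rank_des == 1 and batch[0].rank_uti == 1
        assert batch[1].des == 0.0 and batch[1].uti == 0.0

    def test_half_good_half_bad_scaled_params(self):
        batch = [
            _mk_run({"a": (0.9, 0.5), "b": (0.2, 0.2)}),
            _mk_run({"a": (0.2, 0.1), "b": (0.9, 0.6)}),
        ]
        rank_results(batch)
        # run 0: scaled (1, 0, 0, 1); run 1: scaled (0, 1, 1, 0)
        assert batch[0].scaled_params == (1.0, 0.0, 0.0, 1.0)
        assert batch[0].des == 0.0
        assert batch[0].uti == pytest.approx(0.5)
        assert batch[1].uti == pytest.approx(0.5)

    def test_ranks_are_a_permutation(self, benchmark_dataset):
        results = stage1_grid(
            [benchmark_dataset], fp_types=["estate", "maccs"], binary_ids=[1, 3, 37]
        )
        assert sorted(r.rank_des for r in results) == list(range(1, len(results) + 1))
        assert sorted(r.rank_uti for r in results) == list(range(1, len(results) + 1))

    def test_dominance_on_randomized_batches(self):
        """If X >= Y on all four scaled parameters with one strict, X scores
        at least as well on DES and strictly better on UTI (1000 batches)."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            size = int(rng.integers(3, 8))
            r2 = rng.uniform(0, 1, (size, 2))
            rmse = rng.uniform(0, 1, (size, 2))
            batch = [
                _mk_run({"a": (r2[i, 0], rmse[i, 0]), "b": (r2[i, 1], rmse[i, 1])})
                for i in range(size)
            ]
            rank_results(batch)
            for x in batch:
                for y in batch:
                    px, py = np.array(x.scaled_params), np.array(y.scaled_params)
                    if (px >= py).all() and (px > py).any():
                        assert x.des >= y.des - 1e-12
                        assert x.uti > y.uti
            for run in batch:
                assert 0.0 <= run.des <= 1.0 and 0.0 <= run.uti <= 1.0

    def test_rmse_shift_invariance(self):
        """Adding a constant to every RMSE leaves both rankings unchanged."""
        rng = np.random.default_rng(4)
        base = [
            _mk_run({"a": (rng.uniform(), rng.uniform()), "b": (rng.uniform(), rng.uniform())})
            for _ in range(8)
        ]
        shifted = [
            _mk_run(
                {
                    name: (m.r2, m.rmse + 5.0)
                    for name, m in run.metrics.items()
                }
            )
            for run in base
        ]
        rank_results(base)
        rank_results(shifted)
        assert [r.rank_des for r in base] == [r.rank_des for r in shifted]
        assert [r.rank_uti for r in base] == [r.rank_uti for r in shifted]

    def test_zero_spread_metric_warns_and_sets_one(self):
        batch = [
            _mk_run({"a": (0.5, 0.3), "b": (0.9, 0.1)}),
            _mk_run({"a": (0.5, 0.5), "b": (0.4, 0.2)}),
        ]
        with pytest.warns(UserWarning, match="zero spread"):
            rank_results(batch)
        assert batch[0].scaled_params[0] == 1.0
        assert batch[1].scaled_params[0] == 1.0

    def test_agreeing_prefix_reported(self, benchmark_dataset):
        results = stage1_grid(
            [benchmark_dataset], fp_types=["estate", "maccs"], binary_ids=[1, 3, 37, 44]
        )
        prefix = agreeing_top_prefix(results)
        assert 0 <= prefix <= len(results)


class TestResultsCsv:
    def test_csv_is_deterministic(self, tmp_path, benchmark_dataset):
        paths = []
        for run_index in (1, 2):
            results = stage1_grid(
                [benchmark_dataset], fp_types=["estate"], binary_ids=[1, 3, 37]
            )
            path = tmp_path / f"out{run_index}.csv"
            write_results_csv(results, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()
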