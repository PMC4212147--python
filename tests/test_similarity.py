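import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from binary_oracle import oracle_binary
from nonbinary_oracle import oracle_nonbinary
from chemsi.fingerprints import BitFingerprint, FingerprintType
from chemsi.similarity import (
    BINARY_COEFFICIENTS,
    NONBINARY_COEFFICIENTS,
    ConfusionCounts,
    SimilarityConfig,
    SimilarityError,
    SimilarityWeights,
    binary_similarity,
    combine_components,
    combined_similarity,
    component_similarities,
    compute_keys,
    confusion_counts,
    default_config,
    load_config,
    nonbinary_similarity,
)

FT = FingerprintType("maccs", 166)


def _fp(bits, ft=FT):
    return BitFingerprint(ft, tuple(bits))


class TestConfusionCounts:
    def test_identity(self):
        k = confusion_counts(_fp(range(10)), _fp(range(10)))
        assert (k.a, k.b, k.c, k.d) == (10, 0, 0, 156)

    def test_small_example(self):
        ft = FingerprintType("toy", 6)
        k = confusion_counts(_fp([0, 1], ft), _fp([0, 2], ft))
        assert (k.a, k.b, k.c, k.d) == (1, 1, 1, 3)

    def test_length_mismatch(self):
        with pytest.raises(SimilarityError, match="mismatch"):
            confusion_counts(_fp([0]), _fp([0], FingerprintType("estate", 79)))

    def test_exhaustive_length_four(self):
        """All 256 pairs of length-4 vectors against a per-position tally."""
        ft = FingerprintType("toy4", 4)
        for x_bits in itertools.product([0, 1], repeat=4):
            for y_bits in itertools.product([0, 1], repeat=4):
                x = _fp([i for i, v in enumerate(x_bits) if v], ft)
                y = _fp([i for i, v in enumerate(y_bits) if v], ft)
                k = confusion_counts(x, y)
                tally = {"a": 0, "b": 0, "c": 0, "d": 0}
                for xv, yv in zip(x_bits, y_bits):
                    tally["a" if xv and yv else "b" if xv else "c" if yv else "d"] += 1
                assert (k.a, k.b, k.c, k.d) == tuple(tally.values())

    def test_argument_swap_exchanges_b_and_c(self):
        ft = FingerprintType("toy8", 8)
        x, y = _fp([0, 1, 2], ft), _fp([2, 3], ft)
        kxy, kyx = confusion_counts(x, y), confusion_counts(y, x)
        assert (kxy.a, kxy.d) == (kyx.a, kyx.d)
        assert (kxy.b, kxy.c) == (kyx.c, kyx.b)


class TestBinaryCoefficients:
    def test_registry_is_complete(self):
        assert sorted(BINARY_COEFFICIENTS) == list(range(1, 45))
        assert BINARY_COEFFICIENTS[37].name == "Maxwell-Pilliner"
        assert BINARY_COEFFICIENTS[3].name == "Jaccard/Tanimoto"

    def test_exhaustive_oracle_agreement(self):
        """Every coefficient agrees with the independently coded formula table
        over every confusion quadruple with p <= 12, and stays in [0,1]."""
        for a in range(13):
            for b in range(13 - a):
                for c in range(13 - a - b):
                    for d in range(13 - a - b - c):
                        if a + b + c + d == 0:
                            continue
                        for cid, coefficient in BINARY_COEFFICIENTS.items():
                            got = float(coefficient.evaluate(a, b, c, d))
                            assert 0.0 <= got <= 1.0
                            assert got == pytest.approx(
                                oracle_binary(cid, a, b, c, d), abs=1e-12
                            ), (cid, a, b, c, d)

    def test_jaccard_identity(self):
        assert binary_similarity(3, ConfusionCounts(10, 0, 0, 156)) == 1.0

    def test_simple_matching_example(self):
        assert binary_similarity(1, ConfusionCounts(1, 1, 1, 3)) == pytest.approx(4 / 6)

    def test_maxwell_pilliner_self_similarity(self):
        assert binary_similarity(37, ConfusionCounts(7, 0, 0, 100)) == 1.0

    def test_self_unit_flag_is_empirically_correct(self):
        """The registry flag matches observed behaviour on identical inputs
        with a > 0 and d > 0."""
        for cid, coefficient in BINARY_COEFFICIENTS.items():
            values = [float(coefficient.evaluate(a, 0, 0, d)) for a, d in [(3, 9), (1, 50), (20, 2)]]
            if coefficient.self_unit:
                assert all(v == 1.0 for v in values), cid
            else:
                assert any(v < 1.0 for v in values), cid

    def test_symmetric_under_argument_exchange(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 20, size=4)
            if a + b + c + d == 0:
                continue
            for cid, coefficient in BINARY_COEFFICIENTS.items():
                assert float(coefficient.evaluate(a, b, c, d)) == pytest.approx(
                    float(coefficient.evaluate(a, c, b, d)), abs=1e-14
                )

    def test_unknown_id(self):
        with pytest.raises(SimilarityError, match="unknown binary"):
            binary_similarity(45, ConfusionCounts(1, 1, 1, 1))


class TestNonBinaryCoefficients:
    def test_registry_codes(self):
        assert [NONBINARY_COEFFICIENTS[i].code for i in range(1, 7)] == [
            "MC", "Div", "BC", "Dice", "SS1", "Cos",
        ]

    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((2, 0), (0, 2), 0.0),
            ((1, 2, 3), (2, 2, 2), 1 - 2 / 12),
        ],
    )
    def test_bray_curtis_examples(self, x, y, expected):
        assert nonbinary_similarity(3, x, y) == pytest.approx(expected)

    def test_random_vector_oracle_agreement(self):
        """All six coefficients agree with direct formula evaluation on 10^4
        random nonnegative vectors and stay in [0,1]."""
        rng = np.random.default_rng(1234)
        for _ in range(10_000 // 6):
            n = int(rng.integers(1, 40))
            x = np.round(rng.uniform(0, 10, n) * (rng.random(n) > 0.25), 4)
            y = np.round(rng.uniform(0, 10, n) * (rng.random(n) > 0.25), 4)
            for cid in range(1, 7):
                got = nonbinary_similarity(cid, x, y)
                assert 0.0 <= got <= 1.0
                assert got == pytest.approx(
                    oracle_nonbinary(cid, list(x), list(y)), abs=1e-10
                ), cid

    def test_negative_component_rejected(self):
        with pytest.raises(SimilarityError, match="nonnegative"):
            nonbinary_similarity(3, [1, -1], [0, 1])

    def test_length_mismatch(self):
        with pytest.raises(SimilarityError, match="mismatch"):
            nonbinary_similarity(1, [1, 2], [1, 2, 3])


class TestWeights:
    def test_sum_constraint(self):
        with pytest.raises(SimilarityError, match="sum to 1"):
            SimilarityWeights(0.5, 0.5, 0.5, 0.5)

    def test_valid(self):
        w = SimilarityWeights(0.4, 0.35, 0.1, 0.15)
        assert w.as_tuple() == (0.4, 0.35, 0.1, 0.15)

    def test_config_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yml"
        path.write_text(
            "fingerprint: maccs\nbinary_coefficient: 3\nnonbinary_coefficient: 6\n"
            "weights: {fp: 0.5, cd: 0.2, hd: 0.2, fg: 0.1}\nmode: arithmetic\n"
        )
        config = load_config(path)
        assert config.fingerprint == "maccs"
        assert (config.binary_id, config.nonbinary_id) == (3, 6)
        assert config.weights.as_tuple() == (0.5, 0.2, 0.2, 0.1)
        assert config.mode == "arithmetic"


class TestCombinedSimilarity:
    def test_fingerprint_only_reduction(self, ethanol, benzene):
        """Weights (1,0,0,0) reduce the SI to the bare fingerprint similarity
        in both combination modes."""
        for mode in ("geometric", "arithmetic"):
            config = SimilarityConfig(
                weights=SimilarityWeights(1.0, 0.0, 0.0, 0.0), mode=mode
            )
            ka, kb = compute_keys(ethanol), compute_keys(benzene)
            s_fp = binary_similarity(
                config.binary_id, confusion_counts(ka.fingerprint, kb.fingerprint)
            )
            assert combined_similarity(ka, kb, config) == pytest.approx(s_fp, abs=1e-15)

    def test_closed_form_exponentiation(self):
        weights = SimilarityWeights(0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3)
        si = combine_components((0.81, 1.0, 1.0, 1.0), weights, "geometric")
        assert si == pytest.approx(0.9, abs=1e-12)

    def test_zero_weight_zero_similarity_contributes_one(self):
        weights = SimilarityWeights(1.0, 0.0, 0.0, 0.0)
        assert combine_components((0.5, 0.0, 0.0, 0.0), weights, "geometric") == 0.5

    def test_self_similarity_default_config(self, benchmark_dataset):
        config = default_config()
        for mol in benchmark_dataset.molecules:
            keys = compute_keys(mol, config.fingerprint)
            assert combined_similarity(keys, keys, config) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_all_coefficients(self, benchmark_dataset):
        molecules = benchmark_dataset.molecules
        rng = np.random.default_rng(5)
        keys = [compute_keys(m) for m in molecules]
        for _ in range(40):
            i, j = rng.integers(0, len(molecules), 2)
            for cid in range(1, 45):
                config = SimilarityConfig(binary_id=cid)
                assert combined_similarity(keys[i], keys[j], config) == pytest.approx(
                    combined_similarity(keys[j], keys[i], config), abs=1e-12
                )

    @given(
        components=st.lists(
            st.floats(min_value=0.01, max_value=1.0), min_size=4, max_size=4
        ),
        bump=st.floats(min_value=0.0, max_value=0.3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_weight_monotonicity_geometric(self, components, bump):
        """Shifting weight onto the smallest component similarity (rebalancing
        the rest proportionally) never increases the geometric SI."""
        base = (0.4, 0.35, 0.1, 0.15)
        weakest = min(range(4), key=lambda i: components[i])
        shifted = list(base)
        shifted[weakest] += bump
        rest = 1.0 - shifted[weakest]
        scale = rest / (1.0 - base[weakest])
        for i in range(4):
            if i != weakest:
                shifted[i] = base[i] * scale
        before = combine_components(components, SimilarityWeights(*base), "geometric")
        after = combine_components(components, SimilarityWeights(*shifted), "geometric")
        assert after <= before + 1e-12

    def test_component_range_on_random_molecule_pairs(self, benchmark_dataset):
        keys = [compute_keys(m) for m in benchmark_dataset.molecules]
        config = default_config()
        for i in range(0, len(keys), 3):
            for j in range(i, len(keys), 3):
                for s in component_similarities(keys[i], keys[j], config):
                    assert 0.0 <= s <= 1.0
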