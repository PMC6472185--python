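"""Background thresholding, geNorm stability, housekeeper selection, scaling."""

import numpy as np
import pandas as pd
import pytest

from nctools.exceptions import DomainError, InsufficientControlsError, ValidationError
from nctools.matrix import ExpressionMatrix, geometric_mean
from nctools.normalize import (
    apply_background,
    background_threshold,
    genorm_stability,
    normalize_cartridge,
    scaling_factors,
    select_housekeepers,
)
from nctools.simulate import SimulationSpec, simulate_cartridge

from helpers import (
    background_threshold_bruteforce,
    genorm_m_bruteforce,
    select_housekeepers_bruteforce,
)


def as_matrix(values: np.ndarray, stage="flat") -> ExpressionMatrix:
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    cc = pd.Series("Endogenous", index=df.index, name="code_class")
    return ExpressionMatrix(values=df, code_class=cc, stage=stage)


class TestBackgroundThreshold:
    def test_zero_variance_negatives(self):
        assert background_threshold([10, 10, 10, 10]) == pytest.approx(10.0)

    def test_all_zero_negatives_floor_to_one(self):
        assert background_threshold([0, 0, 0, 0]) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self):
        negs = (8, 12, 10, 14, 6, 9, 11, 10)
        assert background_threshold(negs) == pytest.approx(
            background_threshold_bruteforce(negs), abs=1e-9
        )

    def test_single_negative_is_an_error(self):
        with pytest.raises(InsufficientControlsError):
            background_threshold([10])


class TestApplyBackground:
    def test_counts_below_threshold_are_floored(self):
        matrix = as_matrix(np.array([[3.0], [50.0]]))
        out = apply_background(matrix, pd.Series({"s0": 10.0}))
        assert list(out.values["s0"]) == [10.0, 50.0]
        assert out.stage == "background_corrected"

    def test_matrix_above_threshold_unchanged(self):
        matrix = as_matrix(np.array([[30.0, 40.0], [50.0, 60.0]]))
        out = apply_background(matrix, pd.Series({"s0": 5.0, "s1": 5.0}))
        assert out.values.equals(matrix.values)

    def test_per_column_minima_respect_thresholds(self):
        rng = np.random.default_rng(4)
        matrix = as_matrix(rng.integers(0, 60, (30, 5)).astype(float))
        thresholds = pd.Series(
            {f"s{j}": t for j, t in enumerate([5.0, 12.0, 20.0, 1.0, 33.0])}
        )
        out = apply_background(matrix, thresholds)
        for col, t in thresholds.items():
            assert out.values[col].min() >= t

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(ValidationError):
            apply_background(as_matrix(np.ones((2, 2))), pd.Series({"s0": 1.0}))


class TestGenormStability:
    def test_proportional_genes_have_zero_m(self):
        x = np.array([[10.0, 40.0, 25.0], [30.0, 120.0, 75.0]])  # x2 = 3*x1
        m = genorm_stability(pd.DataFrame(x, index=["a", "b"]))
        assert m["a"] == pytest.approx(0.0, abs=1e-12)
        assert m["b"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("shape", [(4, 6), (20, 8)])
    def test_matches_bruteforce_double_loop(self, shape):
        rng = np.random.default_rng(10)
        values = rng.uniform(5.0, 500.0, shape)
        names = [f"g{i}" for i in range(shape[0])]
        m = genorm_stability(pd.DataFrame(values, index=names))
        oracle = genorm_m_bruteforce(values, names)
        for g in names:
            assert m[g] == pytest.approx(oracle[g], abs=1e-9)

    def test_heavy_noise_gene_attains_maximum_m(self):
        rng = np.random.default_rng(2)
        base = 2.0 ** (8.0 + rng.normal(0, 0.05, (5, 8)))
        noisy = 2.0 ** (8.0 + rng.normal(0, 3.0, (1, 8)))
        values = np.vstack([base, noisy])
        names = [f"g{i}" for i in range(6)]
        m = genorm_stability(pd.DataFrame(values, index=names))
        assert max(m, key=m.get) == "g5"

    def test_invariant_under_per_lane_rescaling(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(10.0, 1000.0, (6, 5))
        lane_scale = np.array([0.25, 1.0, 4.0, 0.5, 2.0])
        m1 = genorm_stability(pd.DataFrame(values, index=list("abcdef")))
        m2 = genorm_stability(pd.DataFrame(values * lane_scale, index=list("abcdef")))
        for g in "abcdef":
            assert m1[g] == pytest.approx(m2[g], abs=1e-9)

    def test_non_positive_values_rejected(self):
        with pytest.raises(DomainError):
            genorm_stability(pd.DataFrame([[1.0, 0.0], [2.0, 3.0]], index=["a", "b"]))


class TestSelectHousekeepers:
    def test_exactly_n_keep_candidates_skips_iteration(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.uniform(10, 100, (3, 4)), index=["a", "b", "c"])
        survivors, m = select_housekeepers(df, n_keep=3)
        assert survivors == ["a", "b", "c"]
        assert set(m) == {"a", "b", "c"}

    def test_noisy_gene_is_eliminated_first(self):
        rng = np.random.default_rng(6)
        lane_profile = 2.0 ** rng.uniform(6, 9, 8)
        covarying = np.outer([1.0, 1.4, 0.7, 2.0, 1.1], lane_profile)
        noisy = 2.0 ** (8.0 + rng.normal(0, 2.0, (1, 8)))
        df = pd.DataFrame(
            np.vstack([covarying, noisy]), index=["h1", "h2", "h3", "h4", "h5", "noisy"]
        )
        survivors, _ = select_housekeepers(df, n_keep=5)
        assert survivors == ["h1", "h2", "h3", "h4", "h5"]

    def test_matches_independent_removal_loop(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(20.0, 800.0, (6, 7))
        names = [f"hk{i}" for i in range(6)]
        survivors, _ = select_housekeepers(pd.DataFrame(values, index=names), n_keep=3)
        assert survivors == select_housekeepers_bruteforce(values, names, 3)

    def test_too_few_candidates_is_an_error(self):
        df = pd.DataFrame(np.ones((2, 4)) * 5, index=["a", "b"])
        with pytest.raises(ValidationError):
            select_housekeepers(df, n_keep=3)


class TestScalingFactors:
    def test_identical_lane_profiles_give_unit_factors(self):
        df = pd.DataFrame(
            np.tile([[100.0], [400.0], [250.0]], (1, 4)), columns=list("wxyz")
        )
        _, sf = scaling_factors(df)
        assert np.allclose(sf, 1.0)

    def test_hand_computed_two_lane_case(self):
        # lane geomeans (100, 400) -> A = 250 -> SF = (2.5, 0.625)
        df = pd.DataFrame({"l1": [50.0, 200.0], "l2": [200.0, 800.0]})
        g, sf = scaling_factors(df)
        assert g["l1"] == pytest.approx(geometric_mean([50.0, 200.0]))
        assert sf["l1"] == pytest.approx(2.5)
        assert sf["l2"] == pytest.approx(0.625)

    def test_scaled_geomeans_collapse_to_the_common_mean(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.uniform(10, 1000, (5, 9)))
        g, sf = scaling_factors(df)
        products = g * sf
        assert np.allclose(products, products.iloc[0], rtol=1e-12)


class TestNormalizeCartridge:
    def test_single_lane_is_identity_after_background(self):
        cartridge, _ = simulate_cartridge(
            SimulationSpec(n_lanes=1, n_endogenous=20, n_housekeeping=5, seed=1)
        )
        result = normalize_cartridge(cartridge)
        assert np.allclose(result.scaling_factors, 1.0)

    def test_planted_lane_effects_are_equalized(self):
        cartridge, _ = simulate_cartridge(
            SimulationSpec(
                n_lanes=3,
                n_endogenous=30,
                n_housekeeping=6,
                lane_effects=(0.5, 1.0, 2.0),
                hk_noise_sd=0.01,
                seed=2,
            )
        )
        result = normalize_cartridge(cartridge)
        hk = result.matrix.of_class("Housekeeping")
        selected = hk.values.loc[list(result.selected_housekeepers)]
        geomeans = geometric_mean(selected.to_numpy(), axis=0)
        assert np.allclose(geomeans, geomeans[0], rtol=1e-9)

    def test_full_cartridge_keeps_at_least_three_housekeepers(self, normalized_default):
        assert len(normalized_default.selected_housekeepers) >= 3

    def test_controls_excluded_from_matrix_but_retained(self, normalized_small):
        assert set(normalized_small.matrix.code_class) == {"Endogenous", "Housekeeping"}
        assert set(normalized_small.control_matrix.code_class) == {"Positive", "Negative"}

    def test_scaling_factors_recover_inverse_lane_effects(self):
        effects = (0.25, 0.5, 1.0, 1.5, 2.0, 4.0)
        cartridge, truth = simulate_cartridge(
            SimulationSpec(
                n_lanes=6,
                n_endogenous=30,
                n_housekeeping=10,
                lane_effects=effects,
                hk_noise_sd=1e-3,
                seed=3,
            )
        )
        result = normalize_cartridge(cartridge)
        r = np.corrcoef(result.scaling_factors, 1.0 / np.asarray(effects))[0, 1]
        assert r > 0.99
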