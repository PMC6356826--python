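import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridity import CountMatrix
from hybridity.data_model import ValidationError
from hybridity.de import (
    bh_adjust,
    estimate_dispersion,
    finish_contrast,
    moderate_dispersion,
    normalize,
    run_contrast,
    size_factors,
    wald_contrast,
)
from hybridity.synthetic import SimConfig, _nb_draw, simulate_counts

from .conftest import random_count_matrix


def median_of_ratios_oracle(counts: pd.DataFrame) -> np.ndarray:
    """Independent, naive median-of-ratios implementation."""
    factors = []
    ref = [g for g in counts.index if (counts.loc[g] > 0).all()]
    geo = {g: float(np.exp(np.mean(np.log(counts.loc[g])))) for g in ref}
    for s in counts.columns:
        ratios = sorted(counts.at[g, s] / geo[g] for g in ref)
        factors.append(float(np.median(ratios)))
    return np.array(factors)


class TestSizeFactors:
    def test_doubling_a_sample_doubles_its_factor(self):
        a = pd.Series([10, 20, 5], index=["g1", "g2", "g3"])
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        f = size_factors(counts)
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_identical_samples_get_unit_factors(self):
        a = pd.Series([10, 20, 5], index=["g1", "g2", "g3"])
        counts = pd.DataFrame({"A": a, "B": a, "C": a})
        assert np.allclose(size_factors(counts), 1.0)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        cm = random_count_matrix(rng, n_genes=5, n_samples=3)
        assert np.allclose(size_factors(cm.counts), median_of_ratios_oracle(cm.counts))

    def test_error_without_all_positive_reference_gene(self):
        counts = pd.DataFrame({"A": [0, 5], "B": [3, 0]}, index=["g1", "g2"])
        with pytest.raises(ValidationError):
            size_factors(counts)


class TestNormalize:
    def test_factor_two_halves_a_column(self):
        counts = pd.DataFrame({"A": [10, 4], "B": [20, 8]}, index=["g1", "g2"])
        norm = normalize(counts, pd.Series({"A": 1.0, "B": 2.0}))
        assert (norm["B"] == counts["A"]).all()

    def test_unit_factors_are_identity(self):
        counts = pd.DataFrame({"A": [10, 4]}, index=["g1", "g2"])
        norm = normalize(counts, pd.Series({"A": 1.0}))
        assert (norm["A"] == counts["A"]).all()

    def test_equal_depth_libraries_keep_column_sums(self):
        cfg = SimConfig(n_genes=400, size_factor_range=(1.0, 1.0), seed=8)
        cm, _ = simulate_counts(cfg)
        f = size_factors(cm.counts)
        assert np.allclose(f, 1.0, atol=0.2)
        norm = normalize(cm.counts, f)
        assert np.allclose(norm.sum(), cm.counts.sum(), rtol=0.15)


class TestDispersion:
    def test_zero_within_group_variance_hits_floor(self):
        norm = pd.DataFrame(
            {"a1": [10, 100], "a2": [10, 100], "b1": [10, 100], "b2": [10, 100]},
            index=["g1", "g2"],
        )
        d = estimate_dispersion(norm, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert (d["alpha"] == 1e-8).all()

    def test_poisson_like_data_stays_near_floor(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(500.0, size=(300, 50))
        norm = pd.DataFrame(x, columns=[f"s{i}" for i in range(50)])
        d = estimate_dispersion(norm, {"A": list(norm.columns)})
        # mean MoM alpha for Poisson data is ~0 (half the estimates floor)
        assert d["alpha"].median() < 0.005

    def test_estimator_consistent_at_large_n(self):
        rng = np.random.default_rng(1)
        alpha_true, n = 0.2, 50
        mu = np.full(500, 200.0)
        xa = np.column_stack([_nb_draw(rng, mu, np.full(500, alpha_true)) for _ in range(n)])
        norm = pd.DataFrame(xa, columns=[f"s{i}" for i in range(n)])
        d = estimate_dispersion(norm, {"A": list(norm.columns)})
        assert d["alpha"].mean() == pytest.approx(alpha_true, rel=0.2)

    def test_all_zero_genes_flagged_untestable(self):
        norm = pd.DataFrame({"a1": [0, 5], "a2": [0, 6]}, index=["g1", "g2"])
        d = estimate_dispersion(norm, {"A": ["a1", "a2"]})
        assert bool(d.loc["g1", "untestable"]) and not bool(d.loc["g2", "untestable"])

    def test_moderation_pulls_toward_mean(self):
        d = pd.DataFrame({"alpha": [0.0, 0.4], "untestable": [False, False]})
        m = moderate_dispersion(d, residual_df=6, prior_df=10)
        assert 0 < m["alpha"].iloc[0] < m["alpha"].iloc[1] < 0.4


class TestWald:
    def _norm(self):
        return pd.DataFrame(
            {"a1": [10.0, 0.0], "a2": [10.0, 0.0], "b1": [10.0, 0.0], "b2": [10.0, 0.0]},
            index=["g1", "g2"],
        )

    def test_equal_means_give_zero_lfc_and_p_one(self):
        norm = self._norm()
        alpha = pd.Series(0.1, index=norm.index)
        res = wald_contrast(norm, {"A": ["a1", "a2"], "B": ["b1", "b2"]}, "A", "B", alpha)
        assert res.loc["g1", "log2fc"] == 0.0
        assert res.loc["g1", "p"] == pytest.approx(1.0)

    def test_swapping_groups_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(3)
        norm = pd.DataFrame(
            rng.poisson(50, size=(20, 4)).astype(float),
            columns=["a1", "a2", "b1", "b2"],
        )
        alpha = pd.Series(0.1, index=norm.index)
        groups = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        ab = wald_contrast(norm, groups, "A", "B", alpha)
        ba = wald_contrast(norm, groups, "B", "A", alpha)
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["p"], ba["p"])

    def test_both_means_zero_is_untestable(self):
        norm = self._norm()
        alpha = pd.Series(0.1, index=norm.index)
        res = wald_contrast(norm, {"A": ["a1", "a2"], "B": ["b1", "b2"]}, "A", "B", alpha)
        assert bool(res.loc["g2", "untestable"])
        assert res.loc["g2", "p"] == 1.0


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_p_stay_equal(self):
        q = bh_adjust(np.array([0.2, 0.2, 0.2]))
        assert np.allclose(q, 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200)
    )
    def test_matches_independent_step_up_oracle(self, pvals):
        p = np.array(pvals)

        def oracle(p):
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        assert np.allclose(bh_adjust(p), oracle(p))
        assert (bh_adjust(p) >= p - 1e-12).all()  # q >= p under BH


class TestRunContrast:
    def test_lfc_below_threshold_is_not_de(self):
        table = pd.DataFrame(
            {
                "log2fc": [0.8, 2.0],
                "p": [1e-10, 1e-10],
                "untestable": [False, False],
            },
            index=["g1", "g2"],
        )
        out = finish_contrast(table, alpha=0.05, lfc_min=1.0)
        assert not bool(out.loc["g1", "is_de"]) and bool(out.loc["g2", "is_de"])

    def test_all_null_simulation_yields_almost_no_de(self):
        cfg = SimConfig(n_genes=500, mode_proportions={"null": 1.0}, seed=21)
        cm, _ = simulate_counts(cfg)
        res = run_contrast(cm, "F", "Cross")
        assert res["is_de"].mean() <= 0.01

    def test_scaling_one_sample_leaves_results_invariant(self, balanced_sim):
        """Multiplying one library by k scales its factor by k only."""
        cfg, cm, truth = balanced_sim
        res0 = run_contrast(cm, "F", "L")
        scaled = cm.counts.copy()
        scaled["F_1"] = scaled["F_1"] * 4
        cm2 = CountMatrix(scaled, cm.groups)
        f0, f2 = size_factors(cm.counts), size_factors(cm2.counts)
        # relative to any other library, the scaled factor moves by exactly k
        assert f2["F_1"] / f2["L_1"] == pytest.approx(4.0 * f0["F_1"] / f0["L_1"])
        res2 = run_contrast(cm2, "F", "L")
        # the common k^(1/n) shift only acts through the pseudocount, so
        # well-expressed genes are essentially unchanged
        expressed = (res0["mean_a"] >= 10) & (res0["mean_b"] >= 10)
        assert np.allclose(
            res0.loc[expressed, "log2fc"], res2.loc[expressed, "log2fc"], atol=0.02
        )
        assert np.allclose(res0["log2fc"], res2["log2fc"], atol=0.2)
        assert np.allclose(res0["p"], res2["p"], atol=0.05)

    def test_power_monotone_in_effect_size(self):
        """Empirical power is non-decreasing along a delta ladder."""
        powers = []
        for delta in (0.5, 2.0, 4.0):
            cfg = SimConfig(
                n_genes=1000,
                mode_proportions={"additive": 1.0},
                parental_log2fc=delta,
                n_per_group={"F": 4, "L": 4},
                seed=33,
            )
            cm, _ = simulate_counts(cfg)
            res = run_contrast(cm, "F", "L")
            powers.append(res["is_de"].mean())
        assert powers == sorted(powers)
        assert powers[-1] >= 0.9  # delta=4, n=4 vs 4
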