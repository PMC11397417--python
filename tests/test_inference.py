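import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phytoscore import (
    distance_matrix,
    duncan_mrt,
    mantel_test,
    one_way_anova,
    pearson_matrix,
)
from phytoscore.errors import DesignError, DomainError, ValidationError
from phytoscore.inference import AnovaResult, duncan_significance, p_to_stars

from conftest import make_table


# ---------------------------------------------------------------------------
# Independent brute-force oracle for Duncan's multiple range test:
# a sorted-means span fails if its range does not exceed R_p; every pair
# inside any failing span is declared non-significant (blanket marking),
# which is the step-down protection rule unrolled.
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=None)
def _q_cached(alpha, span, dfw):
    return stats.studentized_range.ppf((1 - alpha) ** (span - 1), span, dfw)


def oracle_significance(means, ns, mse, dfw, alpha=0.05):
    k = len(means)
    nonsig = set()
    for i, j in itertools.combinations(range(k), 2):
        span = j - i + 1
        q = _q_cached(alpha, span, dfw)
        n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
        if not (means[i] - means[j] > q * np.sqrt(mse / n_h)):
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    nonsig.add((a, b))
    sig = np.zeros((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        sig[i, j] = sig[j, i] = (i, j) not in nonsig
    return sig


def letters_consistent(display, sig_sorted):
    """Shared letter iff not significantly different; every group lettered."""
    letters = [set(l) for _, _, l in display.entries]
    if any(not l for l in letters):
        return False
    k = len(letters)
    for i, j in itertools.combinations(range(k), 2):
        share = bool(letters[i] & letters[j])
        if share == bool(sig_sorted[i, j]):
            return False
    return True


def make_anova(means, mse=1.0, n=4, dfw=None):
    k = len(means)
    return AnovaResult(
        variable="x",
        f_stat=1.0,
        df_between=k - 1,
        df_within=dfw if dfw is not None else k * (n - 1),
        p_value=0.5,
        mse=mse,
        group_means={f"G{i}": m for i, m in enumerate(means)},
        group_ns={f"G{i}": n for i in range(k)},
    )


class TestAnova:
    def test_identical_groups(self, two_group_table):
        res = one_way_anova(two_group_table, "x")
        assert res.f_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df_between == 1
        assert res.df_within == 4

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc, 1, 5) for loc in (10, 10.5, 12)]
        t = make_table(
            {"x": np.concatenate(groups)},
            regions=["A"] * 5 + ["B"] * 5 + ["C"] * 5,
        )
        res = one_way_anova(t, "x")
        f_ref, p_ref = stats.f_oneway(*groups)
        assert res.f_stat == pytest.approx(f_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        t = make_table(
            {"x": np.concatenate([1 + rng.normal(0, 1e-4, 4), 11 + rng.normal(0, 1e-4, 4)])},
            regions=["A"] * 4 + ["B"] * 4,
        )
        assert one_way_anova(t, "x").p_value < 1e-6

    def test_single_replicate_group_rejected(self):
        t = make_table({"x": [1.0, 2.0, 3.0]}, regions=["A", "A", "B"])
        with pytest.raises(DesignError):
            one_way_anova(t, "x")

    def test_degenerate_flagged(self):
        t = make_table({"x": [1.0] * 4}, regions=["A", "A", "B", "B"])
        res = one_way_anova(t, "x")
        assert res.degenerate
        assert np.isnan(res.f_stat)

    def test_group_means_and_ns(self, two_group_table):
        res = one_way_anova(two_group_table, "x")
        assert res.group_means == {"A": 2.0, "B": 2.0}
        assert res.group_ns == {"A": 3, "B": 3}


class TestDuncan:
    def test_all_equal_means_single_letter(self):
        display = duncan_mrt(make_anova([1.0, 1.0, 1.0]))
        assert [l for _, _, l in display.entries] == ["a", "a", "a"]

    def test_far_group_isolated(self):
        display = duncan_mrt(make_anova([50.0, 0.1, 0.0], mse=1e-6))
        letters = display.letters()
        sig = oracle_significance([50.0, 0.1, 0.0], [4, 4, 4], 1e-6, 9)
        assert letters_consistent(display, sig)
        assert not (set(letters["G0"]) & set(letters["G1"]))

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_oracle_equivalence_random_configs(self, k):
        rng = np.random.default_rng(100 + k)
        for trial in range(40):
            n = int(rng.integers(2, 5))
            means = np.sort(rng.normal(0, rng.uniform(0.2, 3), k))[::-1]
            if trial % 3 == 0:  # inject exact ties
                means[rng.integers(0, k)] = means[0]
                means = np.sort(means)[::-1]
            mse = float(rng.uniform(0.01, 2.0))
            anova = make_anova(list(means), mse=mse, n=n)
            sig = duncan_significance(
                means, [n] * k, mse, anova.df_within, alpha=0.05
            )
            oracle = oracle_significance(means, [n] * k, mse, anova.df_within)
            np.testing.assert_array_equal(sig, oracle)
            display = duncan_mrt(anova)
            assert letters_consistent(display, sig)

    def test_unbalanced_groups_use_harmonic_mean(self):
        anova = AnovaResult(
            "x", 5.0, 1, 6, 0.05, 1.0,
            {"A": 3.0, "B": 0.0}, {"A": 2, "B": 6},
        )
        display = duncan_mrt(anova)
        n_h = 2 / (1 / 2 + 1 / 6)
        q = stats.studentized_range.ppf(0.95, 2, 6)
        expected_sig = 3.0 > q * np.sqrt(1.0 / n_h)
        shares = bool(
            set(display.letters()["A"]) & set(display.letters()["B"])
        )
        assert shares != expected_sig

    def test_letter_classes_maximal(self):
        # no group can be added to any letter class without creating a
        # significant pair inside it
        rng = np.random.default_rng(42)
        for _ in range(20):
            k = int(rng.integers(3, 7))
            means = np.sort(rng.normal(0, 1.5, k))[::-1]
            anova = make_anova(list(means), mse=0.5, n=3)
            sig = duncan_significance(means, [3] * k, 0.5, anova.df_within)
            display = duncan_mrt(anova)
            classes: dict[str, set[int]] = {}
            for idx, (_, _, ltrs) in enumerate(display.entries):
                for l in ltrs:
                    classes.setdefault(l, set()).add(idx)
            for members in classes.values():
                for outsider in set(range(k)) - members:
                    assert any(sig[outsider, m] for m in members)

    @pytest.mark.parametrize("k", [2, 12])
    def test_protection_level_null_calibration(self, k):
        # under the complete null the probability of ANY false separation
        # equals the protection level alpha_k = 1 - (1-alpha)**(k-1): the
        # full-range span is tested at exactly that level and any separation
        # requires it to reject
        rng = np.random.default_rng(7)
        runs = 400
        n_obs = 4 * k
        expected = 1 - 0.95 ** (k - 1)
        false_separations = 0
        for _ in range(runs):
            x = rng.normal(0, 1, n_obs)
            t = make_table(
                {"x": x - x.min() + 0.1}, regions=[f"M{i // 4}" for i in range(n_obs)]
            )
            display = duncan_mrt(one_way_anova(t, "x"))
            letters = [set(l) for _, _, l in display.entries]
            if any(
                not (letters[i] & letters[j])
                for i, j in itertools.combinations(range(k), 2)
            ):
                false_separations += 1
        rate = false_separations / runs
        mc_se = np.sqrt(expected * (1 - expected) / runs)
        assert abs(rate - expected) <= 4 * mc_se

    def test_degenerate_anova_rejected(self):
        res = make_anova([1.0, 1.0])
        res.degenerate = True
        with pytest.raises(DomainError):
            duncan_mrt(res)


class TestPearson:
    def test_exact_linear(self):
        t = make_table({"x": [1.0, 2.0, 3.0, 4.0], "y": [5.0, 7.0, 9.0, 11.0]})
        res = pearson_matrix(t, ["x", "y"])
        assert res.r.loc["x", "y"] == pytest.approx(1.0)
        assert res.p.loc["x", "y"] < 1e-10
        assert res.stars.loc["x", "y"] == "***"

    def test_independent_null(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(0, 1, 10000), "y": rng.normal(0, 1, 10000)})
        res = pearson_matrix(df)
        assert abs(res.r.loc["x", "y"]) < 0.05

    def test_p_matches_t_cdf(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 20)
        y = x * 0.5 + rng.normal(0, 1, 20)
        res = pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        r = res.r.loc["x", "y"]
        t = r * np.sqrt(18 / (1 - r**2))
        assert res.p.loc["x", "y"] == pytest.approx(2 * stats.t.sf(abs(t), 18), abs=1e-12)
        _, p_ref = stats.pearsonr(x, y)
        assert res.p.loc["x", "y"] == pytest.approx(p_ref, abs=1e-12)

    def test_configured_correlation_recovered(self):
        from phytoscore.synthetic_data import SimulationConfig, generate_study

        cfg = SimulationConfig(seed=11, n_regions=1, n_replicates=4000)
        table, _ = generate_study(cfg)
        res = pearson_matrix(table, ["total_acid", "aa2bg"])
        assert res.r.loc["total_acid", "aa2bg"] == pytest.approx(0.83, abs=0.05)

    def test_zero_variance_flagged_nan(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        res = pearson_matrix(df)
        assert np.isnan(res.r.loc["x", "y"])
        assert res.stars.loc["x", "y"] == ""

    def test_symmetry_and_diag(self, default_table):
        res = pearson_matrix(default_table)
        np.testing.assert_allclose(res.r.to_numpy(), res.r.to_numpy().T)
        np.testing.assert_allclose(np.diag(res.r.to_numpy()), 1.0)

    def test_star_thresholds(self):
        assert p_to_stars(0.2) == ""
        assert p_to_stars(0.04) == "*"
        assert p_to_stars(0.009) == "**"
        assert p_to_stars(0.0009) == "***"


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        df = pd.DataFrame({"x": [1.0, 1.0], "y": [2.0, 2.0]})
        for metric in ("euclidean", "bray_curtis"):
            d = distance_matrix(df, metric=metric)
            np.testing.assert_allclose(d.to_numpy(), 0.0)

    def test_1d_euclidean(self):
        d = distance_matrix(pd.DataFrame({"x": [0.0, 3.0]}))
        assert d.iloc[0, 1] == pytest.approx(3.0)

    def test_bray_curtis_formula(self):
        d = distance_matrix(
            pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]}), metric="bray_curtis"
        )
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_rejects_negative(self):
        df = pd.DataFrame({"a": [-1.0, 0.0], "b": [0.0, 1.0]})
        with pytest.raises(DomainError):
            distance_matrix(df, metric="bray_curtis")

    def test_standardized_euclidean(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [0.0, 100.0, 200.0]})
        d = distance_matrix(df, metric="euclidean", standardize=True)
        # both columns carry identical information after z-scoring
        assert d.iloc[0, 1] == pytest.approx(d.iloc[1, 2])


class TestMantel:
    @staticmethod
    def random_distance(rng, n=10, dim=3):
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(rng.random((n, dim))))

    def test_identity_matrices(self):
        rng = np.random.default_rng(1)
        d = self.random_distance(rng)
        res = mantel_test(d, d, n_permutations=199, seed=2)
        assert res.r_obs == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_matches_scikit_bio_r(self):
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(8)
        x = rng.random((12, 4))
        da = self.random_distance(rng, 12)
        from scipy.spatial.distance import pdist, squareform

        db = squareform(pdist(x))
        r_ref, p_ref, _ = mantel(
            DistanceMatrix(da), DistanceMatrix(db),
            permutations=999, alternative="greater", seed=0,
        )
        res = mantel_test(da, db, n_permutations=999, seed=0)
        assert res.r_obs == pytest.approx(r_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=0.08)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        da = self.random_distance(rng)
        db = self.random_distance(rng)
        perm = rng.permutation(10)
        res1 = mantel_test(da, db, n_permutations=199, seed=5)
        res2 = mantel_test(
            da[np.ix_(perm, perm)], db[np.ix_(perm, perm)],
            n_permutations=199, seed=5,
        )
        assert res1.r_obs == pytest.approx(res2.r_obs, abs=1e-12)
        assert abs(res1.p_value - res2.p_value) < 0.05

    def test_shape_mismatch(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError):
            mantel_test(self.random_distance(rng, 8), self.random_distance(rng, 9),
                        seed=1)

    def test_constant_triangle_flagged(self):
        d = np.ones((5, 5)) - np.eye(5)
        rng = np.random.default_rng(0)
        res = mantel_test(d, self.random_distance(rng, 5), n_permutations=99, seed=1)
        assert not res.r_defined

    def test_seed_required(self):
        rng = np.random.default_rng(0)
        d = self.random_distance(rng)
        with pytest.raises(ValidationError):
            mantel_test(d, d, seed=None)

    def test_planted_shared_gradient_detected(self):
        # mineral panel and a quality variable driven by the same gradient
        from phytoscore import aggregate_regions
        from phytoscore.synthetic_data import SimulationConfig, plant_ordering

        cfg = SimulationConfig(seed=17)
        # plant the gradient in minerals too by reusing quality roles
        from phytoscore.core_data import VariablePanel

        cfg = SimulationConfig(
            seed=17,
            panels=[
                VariablePanel("minerals", ("K", "Ca", "Zn", "Mg"), role="quality"),
                VariablePanel("quality2", ("total_polysaccharide",), role="quality"),
            ],
        )
        table, _ = plant_ordering(cfg, 4.0)
        regional = aggregate_regions(table)
        d_min = distance_matrix(regional, ["K", "Ca", "Zn", "Mg"], metric="bray_curtis")
        d_poly = distance_matrix(regional, ["total_polysaccharide"], metric="euclidean")
        res = mantel_test(d_min, d_poly, n_permutations=999, seed=3)
        assert res.p_value < 0.05
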