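import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import fermcurve as fc


def profiles(v_early, v_late, dt=24.0):
    labels = [f"c{i}" for i in range(len(v_early))]
    return fc.PairedProfiles(labels, np.asarray(v_early, float),
                             np.asarray(v_late, float), dt=dt)


vector_pairs = st.integers(5, 13).flatmap(
    lambda n: st.tuples(
        arrays(float, n, elements=st.floats(-50, 50, width=32)),
        arrays(float, n, elements=st.floats(-50, 50, width=32)),
    )
).filter(lambda p: np.ptp(p[0]) > 1e-3 and np.ptp(p[1]) > 1e-3
         and len(np.unique(p[0])) == len(p[0])
         and len(np.unique(p[1])) == len(p[1]))


class TestSlopeDispersion:
    def test_identical_changes_zero_dispersion(self):
        assert fc.slope_dispersion(profiles([1, 2, 3], [4, 5, 6])) == 0.0

    def test_hand_computed_value(self):
        # |slopes| = (1,2,3)/24; sample sd 1/24, mean 2/24 -> 0.5
        p = profiles([1, 2, 3], [2, 4, 6])
        assert fc.slope_dispersion(p) == pytest.approx(0.5, rel=1e-12)

    def test_invariant_to_dt_and_common_scale(self):
        a, b = [1.0, 2.0, 5.0], [3.0, 1.0, 9.0]
        ref = fc.slope_dispersion(profiles(a, b, dt=24))
        assert fc.slope_dispersion(profiles(a, b, dt=7)) == \
            pytest.approx(ref, rel=1e-12)
        scaled = profiles([10 * x for x in a], [10 * x for x in b])
        assert fc.slope_dispersion(scaled) == pytest.approx(ref, rel=1e-12)

    def test_zero_mean_slope_rejected(self):
        with pytest.raises(ValueError, match="dispersion undefined"):
            fc.slope_dispersion(profiles([1, 2, 3], [1, 2, 3]))


class TestPairedTests:
    def test_no_change_degenerate(self):
        res = fc.paired_tests(profiles([1, 2, 3], [1, 2, 3]))
        assert (res.p_ttest, res.p_wilcoxon) == (1.0, 1.0)
        assert res.flag == "degenerate-no-change"

    def test_uniform_shift_degenerate_large_effect(self):
        res = fc.paired_tests(profiles([1, 2, 3, 4, 5],
                                       [11, 12, 13, 14, 15]))
        assert res.flag == "degenerate-large-effect"
        assert res.p_ttest == 0.0
        assert 0 < res.p_wilcoxon < 0.2

    def test_small_p_for_consistent_change(self):
        rng = np.random.default_rng(0)
        early = rng.uniform(0, 1, 13)
        res = fc.paired_tests(profiles(early, early + 5 + rng.uniform(0, 1, 13)))
        assert res.p_ttest < 1e-6
        assert res.p_wilcoxon == pytest.approx(2 / 2 ** 13, rel=1e-9)


class TestCorrelations:
    def test_perfect_linear_agreement(self):
        r, r_p, rho, rho_p = fc.correlations(
            profiles([1, 2, 3, 4], [2, 4, 6, 8]))
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize("r,expected_p", [
        (0.805, 9.093e-4),
        (0.883, 6.222e-5),
        (0.894, 3.780e-5),
    ])
    def test_pearson_p_from_t_at_n13(self, r, expected_p):
        """Two-sided p of Pearson r at n=13 via t = r sqrt(n-2)/sqrt(1-r^2).

        Reference p-values were computed from unrounded correlations, so
        a three-decimal r reproduces them only to a few percent."""
        from scipy import stats
        t = r * np.sqrt(11 / (1 - r * r))
        p = 2 * stats.t.sf(t, df=11)
        assert p == pytest.approx(expected_p, rel=0.03)
        # the same value emerges from the battery on vectors with that r
        x, y = _vectors_with_correlation(r, n=13, seed=1)
        _, r_p, _, _ = fc.correlations(profiles(x, y))
        assert r_p == pytest.approx(p, rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fc.correlations(profiles([1, 1, 1], [1, 2, 3]))


class TestZscoreAndSimilarity:
    def test_zscore_moments(self):
        z = fc.zscore([3.0, 9.0, 4.4, 7.1, 0.2])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_zscore_of_123(self):
        np.testing.assert_allclose(fc.zscore([1, 2, 3]), [-1, 0, 1],
                                   atol=1e-12)

    def test_identical_profiles_similarity_one(self):
        sims = fc.similarity(profiles([1, 2, 5], [1, 2, 5]))
        assert sims == pytest.approx((1.0, 1.0, 1.0))

    def test_affinely_related_profiles_similarity_one(self):
        # z-scoring removes location/scale, so a positive affine map is
        # an identical profile
        sims = fc.similarity(profiles([1, 2, 5], [10, 30, 90]))
        assert sims == pytest.approx((1.0, 1.0, 1.0))

    def test_negative_cosine_warns(self):
        with pytest.warns(UserWarning, match="cosine"):
            _, _, cos = fc.similarity(profiles([1, 2, 3], [3, 2, 1]))
        assert cos == pytest.approx(-1.0)

    @given(vector_pairs)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_zscore_identities(self, pair):
        """After sample-sd z-scoring, d_eu^2 = 2(n-1)(1-r) and cosine = r."""
        x, y = pair
        p = profiles(x, y)
        n = p.n
        r, *_ = fc.correlations(p)
        ze, zl = fc.zscore(x), fc.zscore(y)
        d2 = float(np.sum((ze - zl) ** 2))
        assert d2 == pytest.approx(2 * (n - 1) * (1 - r), abs=1e-8)
        sims = fc.similarity(p)
        assert sims[2] == pytest.approx(r, abs=1e-10)
        assert 0 < sims[0] <= 1 and 0 < sims[1] <= 1


def _vectors_with_correlation(r, n=13, seed=0):
    """Two vectors whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    x = x - x.mean()
    e = e - e.mean()
    e = e - (e @ x) / (x @ x) * x          # orthogonal to x, zero mean
    x /= np.linalg.norm(x)
    e /= np.linalg.norm(e)
    y = r * x + np.sqrt(1 - r * r) * e
    return x, y


class TestConstructedCorrelation:
    @pytest.mark.parametrize("r", [0.883, 0.805, 0.894, -0.3])
    def test_construction_hits_target_r(self, r):
        x, y = _vectors_with_correlation(r)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(r, abs=1e-12)


class TestRobustnessReport:
    def _three_indicators(self):
        # the concordant indicator barely changes between time-points:
        # equal-magnitude alternating shifts give near-zero dispersion,
        # symmetric differences (high paired-test p) and r close to 1
        rng = np.random.default_rng(7)
        base = rng.uniform(1, 10, 13)
        shifts = 0.1 * (-1.0) ** np.arange(13) + rng.normal(0, 0.005, 13)
        concordant = profiles(base, base + shifts)
        noisy1 = profiles(base, rng.permutation(base))
        noisy2 = profiles(base, base + rng.normal(2, 4, 13))
        return {"ratio": concordant, "scfa": noisy1, "nh3": noisy2}

    def test_identical_indicators_all_tie(self):
        p = profiles([1.0, 4.0, 2.5, 8.0], [2.0, 5.0, 3.0, 7.0])
        report = fc.robustness_report({"a": p, "b": p, "c": p})
        assert report.best.all().all()

    def test_concordant_indicator_flagged_best(self):
        report = fc.robustness_report(self._three_indicators())
        assert int(report.best.loc["ratio"].sum()) >= 8

    def test_report_shape_and_columns(self):
        report = fc.robustness_report(self._three_indicators())
        from fermcurve.robustness import STATISTICS
        assert list(report.stats.index) == ["ratio", "scfa", "nh3"]
        assert list(report.stats.columns) == list(STATISTICS)
        frame = report.to_frame()
        assert "best" in frame.columns

    def test_label_mismatch_rejected(self):
        a = profiles([1, 2, 3], [2, 3, 4])
        b = fc.PairedProfiles(["x", "y", "z"], [1, 2, 3], [2, 3, 4])
        with pytest.raises(ValueError, match="labels"):
            fc.robustness_report({"a": a, "b": b})

    def test_minimum_two_indicators(self):
        with pytest.raises(ValueError, match="at least 2"):
            fc.robustness_report({"a": profiles([1, 2, 3], [2, 3, 4])})
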