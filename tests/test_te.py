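"""TE statistics: ratios, z-classification, Mann-Whitney, correlations."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ribosig.te import (
    delta_te,
    mann_whitney_u,
    replicate_correlation,
    robust_filter,
    translation_efficiency,
    zscore_classify,
)


class TestRatios:
    @pytest.mark.parametrize("rf,mrna,expected", [(8.0, 4.0, 2.0), (0.0, 5.0, 0.0)])
    def test_translation_efficiency(self, rf, mrna, expected):
        assert translation_efficiency(rf, mrna) == expected

    def test_zero_mrna_is_unquantified(self):
        assert math.isnan(translation_efficiency(3.0, 0.0))

    @pytest.mark.parametrize("t,c,ratio,log2", [
        (1.0, 4.0, 0.25, -2.0), (3.0, 3.0, 1.0, 0.0), (4.0, 1.0, 4.0, 2.0)])
    def test_delta_te(self, t, c, ratio, log2):
        assert delta_te(t, c) == (pytest.approx(ratio), pytest.approx(log2))

    def test_delta_te_nonpositive_input_unquantified(self):
        assert all(math.isnan(v) for v in delta_te(0.0, 4.0))
        assert all(math.isnan(v) for v in delta_te(2.0, -1.0))


class TestZScoreClassify:
    def test_hand_computed_outlier(self):
        """Nine zeros and one -3: mean -0.3, population sd 0.9, outlier z = -3."""
        res = zscore_classify([0.0] * 9 + [-3.0])
        assert res.zscore.iloc[-1] == pytest.approx(-3.0)
        assert res.klass.iloc[-1] == "decreased"
        assert (res.klass.iloc[:9] == "insensitive").all()

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning):
            res = zscore_classify([1.0] * 5)
        assert (res.klass == "insensitive").all()
        assert (res.zscore == 0).all()

    def test_negation_swaps_classes(self, rng):
        x = rng.normal(0, 1, 200)
        a = zscore_classify(x)
        b = zscore_classify(-x)
        assert ((a.klass == "decreased") == (b.klass == "increased")).all()

    def test_zscores_are_standardized_and_order_invariant(self, rng):
        x = np.concatenate([rng.normal(0, 0.4, 500), [np.nan, np.inf]])
        res = zscore_classify(x)
        q = res.zscore.dropna()
        assert q.mean() == pytest.approx(0.0, abs=1e-9)
        assert q.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert (res.klass.iloc[-2:] == "unquantified").all()
        perm = rng.permutation(len(x))
        counts = zscore_classify(x[perm]).klass.value_counts()
        assert counts.equals(res.klass.value_counts())


class TestRobustFilter:
    def test_threshold_applies_to_every_library(self):
        import pandas as pd

        counts = pd.DataFrame({"a": [40, 40, 0], "b": [40, 31, 40]})
        keep = robust_filter(counts, min_count=32)
        assert keep.tolist() == [True, False, False]

    def test_zero_threshold_keeps_all(self):
        import pandas as pd

        counts = pd.DataFrame({"a": [0, 5], "b": [1, 2]})
        assert robust_filter(counts, min_count=0).all()


def _u_by_pairwise(x, y):
    """Independent U: count pairwise wins (ties count half)."""
    u = 0.0
    for xi in x:
        for yi in y:
            u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
    return u


def _p_by_enumeration(x, y):
    pooled = list(x) + list(y)
    nx = len(x)
    mu = nx * len(y) / 2
    dev = abs(_u_by_pairwise(x, y) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(_u_by_pairwise(xs, ys) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_textbook_example(self):
        res = mann_whitney_u([1, 2], [3, 4], mode="exact")
        assert res.u == 0
        assert res.p_two_sided == pytest.approx(2 / 6)

    def test_all_ties_give_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="exact")
        assert res.p_two_sided == 1.0

    def test_u_complement_identity(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        a = mann_whitney_u(x, y, mode="normal")
        b = mann_whitney_u(y, x, mode="normal")
        assert a.u + b.u == pytest.approx(len(x) * len(y))
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.lists(st.integers(0, 4), min_size=1, max_size=5),
           st.lists(st.integers(0, 4), min_size=1, max_size=5))
    def test_exact_mode_equals_enumeration(self, x, y):
        res = mann_whitney_u(x, y, mode="exact")
        assert res.u == pytest.approx(_u_by_pairwise(x, y))
        assert res.p_two_sided == pytest.approx(_p_by_enumeration(x, y))

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            x = rng.choice(1000, size=5, replace=False) / 7.0
            y = rng.choice(2000, size=6, replace=False) / 7.0 + 0.01
            ours = mann_whitney_u(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_close_to_exact(self, rng):
        for _ in range(10):
            x, y = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
            pe = mann_whitney_u(x, y, mode="exact").p_two_sided
            pn = mann_whitney_u(x, y, mode="normal").p_two_sided
            assert abs(pe - pn) < 0.02


class TestReplicateCorrelation:
    def test_identical_vectors(self):
        assert replicate_correlation([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        v = np.array([1.0, -2.0, 3.0, -4.0])
        assert replicate_correlation(v, -v, log_transform=False) == pytest.approx(-1.0)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            replicate_correlation([1, 2], [1, 2])

    def test_matches_noise_model_prediction(self, small_experiment):
        """Observed replicate r agrees with the lognormal/NB variance-ratio
        prediction r = Var(signal) / (Var(signal) + mean Var(noise))."""
        from ribosig.simulate import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(n_genes=1500, library_size=2_000_000, seed=9)
        txome, counts = simulate_experiment(cfg)
        a = counts[("dmso", "mrna", 0)].to_numpy(dtype=float)
        b = counts[("dmso", "mrna", 1)].to_numpy(dtype=float)
        keep = (a > 0) & (b > 0)
        a, b = a[keep], b[keep]
        r_obs = replicate_correlation(a, b, log_transform=True, eps=0.0)
        mu = (a + b) / 2
        noise_var = (1.0 / mu + cfg.nb_dispersion) / np.log(2) ** 2
        total_var = np.var(np.log2(mu))  # signal + half the noise
        signal_var = total_var - noise_var.mean() / 2
        r_pred = signal_var / (signal_var + noise_var.mean())
        assert r_obs == pytest.approx(r_pred, abs=0.03)
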