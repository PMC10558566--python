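"""The adapted Intervals Method: trimming, transform, thresholds,
volume-fraction profiles, PCA, and interval-count convergence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mandibite.errors import DegenerateFieldError, ParameterError
from mandibite.fem import ElementStressField
from mandibite.intervals import (
    IntervalConfig,
    choose_interval_count,
    interval_profile,
    log_stress,
    pca_profiles,
    read_intervals_table,
    scenario_profiles,
    scenario_threshold,
    select_interval_count,
    trim_top,
    weighted_quantile,
)


def field(values, volumes=None, ids=None, is_log=False):
    values = np.asarray(values, dtype=float)
    volumes = np.ones_like(values) if volumes is None else np.asarray(volumes, float)
    ids = np.arange(len(values)) if ids is None else np.asarray(ids)
    return ElementStressField(ids, values, volumes, is_log=is_log)


class TestTrim:
    def test_count_arithmetic(self):
        f = field(np.linspace(1, 2, 100))
        assert len(trim_top(f, 0.02)) == 98

    def test_zero_fraction_is_identity(self):
        f = field([3.0, 1.0, 2.0])
        t = trim_top(f, 0.0)
        assert np.array_equal(t.von_mises, f.von_mises)
        assert np.array_equal(t.element_id, f.element_id)

    def test_removes_highest_by_sort_oracle(self):
        f = field(np.arange(1.0, 11.0))
        t = trim_top(f, 0.2)
        # brute-force oracle: sort descending, drop ceil(0.2*10)=2
        expected = sorted(np.arange(1.0, 11.0))[:-2]
        assert sorted(t.von_mises) == expected

    def test_tie_break_removes_higher_id_first(self):
        f = field([5.0, 5.0, 5.0, 1.0], ids=[10, 11, 12, 13])
        t = trim_top(f, 0.25)  # remove exactly one element
        assert 12 not in t.element_id
        assert set(t.element_id) == {10, 11, 13}

    def test_invalid_fraction(self):
        with pytest.raises(ParameterError):
            trim_top(field([1.0]), 1.0)

    @given(st.floats(0.0, 0.9), st.floats(0.0, 0.9))
    @settings(max_examples=30, deadline=None)
    def test_trim_monotonicity(self, p1, p2):
        """More trimming never increases the maximum retained stress."""
        rng = np.random.default_rng(7)
        f = field(rng.lognormal(size=50))
        lo, hi = sorted([p1, p2])
        assert trim_top(f, hi).von_mises.max() <= trim_top(f, lo).von_mises.max()


class TestLogStress:
    def test_closed_forms_and_order(self):
        f = field([1.0, np.e, 10.0])
        g = log_stress(f)
        assert g.von_mises[0] == pytest.approx(0.0)
        assert g.von_mises[1] == pytest.approx(1.0)
        assert np.array_equal(np.argsort(g.von_mises), np.argsort(f.von_mises))

    def test_zero_flooring_logged(self, caplog):
        f = field([0.0, 2.0, 4.0])
        with caplog.at_level("WARNING"):
            g = log_stress(f)
        assert "flooring 1" in caplog.text
        assert g.von_mises[0] == pytest.approx(np.log(2.0))

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateFieldError):
            log_stress(field([0.0, 0.0]))


class TestThreshold:
    def test_equal_volume_percentile(self):
        pool = field(np.arange(1.0, 101.0))
        assert scenario_threshold([pool], 0.15) == 85.0

    def test_tail_to_zero_gives_maximum(self):
        pool = field(np.arange(1.0, 101.0))
        assert scenario_threshold([pool], 1e-9) == 100.0

    def test_pooling_ignores_specimen_identity(self):
        rng = np.random.default_rng(2)
        a = field(rng.uniform(0, 1, 40), rng.uniform(0.5, 2, 40))
        b = field(rng.uniform(5, 6, 60), rng.uniform(0.5, 2, 60))
        merged = field(
            np.concatenate([a.von_mises, b.von_mises]),
            np.concatenate([a.volume, b.volume]),
        )
        assert scenario_threshold([a, b], 0.15) == scenario_threshold(
            [merged], 0.15
        )

    def test_volume_weighted_against_cumsum_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=200)
        w = rng.uniform(0.1, 3.0, 200)
        q = 0.85
        got = weighted_quantile(v, w, q)
        order = np.argsort(v)
        cum = np.cumsum(w[order]) / w.sum()
        expected = v[order][np.searchsorted(cum, q)]
        assert got == expected

    def test_empty_pool(self):
        with pytest.raises(ParameterError):
            scenario_threshold([], 0.15)


class TestIntervalProfile:
    def test_uniform_field_single_interval(self):
        f = field([0.3] * 5, is_log=True)
        p = interval_profile(f, 10, 0.0, 1.0)
        # width = 1/9, so 0.3 lands in interval index 2; all volume there
        assert p.fractions[2] == pytest.approx(1.0)
        assert p.fractions.sum() == pytest.approx(1.0)

    def test_hand_assignment(self):
        f = field([0.1, 0.4, 0.6, 0.9], is_log=True)
        p = interval_profile(f, 2, 0.0, 0.8)
        assert np.allclose(p.fractions, [0.75, 0.25])

    def test_below_lower_clamped_with_warning(self, caplog):
        f = field([-1.0, 0.5], is_log=True)
        with caplog.at_level("WARNING"):
            p = interval_profile(f, 4, 0.0, 1.0)
        assert "clamping 1" in caplog.text
        assert p.fractions[0] == pytest.approx(0.5)

    def test_matches_brute_force_binning_oracle(self):
        rng = np.random.default_rng(11)
        n = 1000
        v = rng.normal(0.0, 2.0, n)
        w = rng.uniform(0.2, 3.0, n)
        f = field(v, w, is_log=True)
        K, lo, thr = 15, -3.0, 3.0
        p = interval_profile(f, K, lo, thr)
        # element-by-element oracle
        width = (thr - lo) / (K - 1)
        acc = np.zeros(K)
        for vi, wi in zip(v, w):
            if vi >= thr:
                k = K - 1
            else:
                k = int((max(vi, lo) - lo) // width)
                k = min(max(k, 0), K - 2)
            acc[k] += wi
        assert np.array_equal(p.fractions, acc / w.sum())

    @given(st.integers(2, 30), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_fractions_conserve_volume(self, K, seed):
        rng = np.random.default_rng(seed)
        f = field(rng.normal(size=50), rng.uniform(0.1, 1, 50), is_log=True)
        p = interval_profile(f, K, -5.0, 5.0)
        assert abs(p.fractions.sum() - 1.0) <= 1e-9
        assert (p.fractions >= 0).all()

    def test_invalid_bounds(self):
        with pytest.raises(ParameterError):
            interval_profile(field([1.0], is_log=True), 5, 2.0, 1.0)


class TestPCA:
    def _profiles(self, n=10, k=15, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.dirichlet(np.ones(k), size=n),
            index=[f"s{i}" for i in range(n)],
            columns=[f"interval_{i + 1}" for i in range(k)],
        )

    def test_variance_sums_to_100(self):
        r = pca_profiles(self._profiles())
        assert r.variance_explained.sum() == pytest.approx(100.0, abs=1e-6)

    def test_components_orthogonal(self):
        r = pca_profiles(self._profiles())
        L = r.loadings.to_numpy()
        G = L.T @ L
        assert np.allclose(G, np.diag(np.diag(G)), atol=1e-10)

    def test_duplicated_specimens_have_identical_scores(self):
        p = self._profiles()
        p2 = pd.concat([p, p.iloc[[2]].rename(index={"s2": "dup"})])
        r = pca_profiles(p2)
        assert np.allclose(r.scores.loc["s2"], r.scores.loc["dup"])

    def test_zero_variance_interval_dropped(self, caplog):
        p = self._profiles()
        p["interval_1"] = 0.0
        with caplog.at_level("WARNING"):
            r = pca_profiles(p)
        assert r.dropped_intervals == ["interval_1"]
        assert "interval_1" not in r.loadings.index

    def test_deterministic(self):
        p = self._profiles(seed=5)
        a, b = pca_profiles(p), pca_profiles(p)
        assert np.array_equal(a.scores.to_numpy(), b.scores.to_numpy())

    def test_needs_three_specimens(self):
        with pytest.raises(ParameterError):
            pca_profiles(self._profiles(n=2))

    def test_reads_external_intervals_table(self, tmp_path):
        p = self._profiles()
        path = tmp_path / "iv.csv"
        (100.0 * p).to_csv(path)  # percentages, as published tables use
        back = read_intervals_table(path)
        assert np.allclose(back.to_numpy(), p.to_numpy())
        r = pca_profiles(back)
        assert r.variance_explained.sum() == pytest.approx(100.0, abs=1e-6)


def synthetic_scenario_fields(n_specimens=6, seed=0):
    """Log-normal stress fields with specimen-specific spread, mimicking
    solved bite simulations of differently shaped specimens."""
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_specimens):
        n = int(rng.integers(400, 800))
        mu = rng.uniform(-0.5, 1.5)
        sd = rng.uniform(0.4, 1.2)
        out[f"s{i}"] = field(
            np.exp(rng.normal(mu, sd, n)), rng.uniform(0.5, 2.0, n)
        )
    return out


class TestScenarioPipeline:
    def test_profiles_sum_to_one(self):
        fields = synthetic_scenario_fields()
        df, layout = scenario_profiles(fields, IntervalConfig())
        assert np.allclose(df.sum(axis=1), 1.0, atol=1e-9)
        assert layout["lower"] < layout["threshold"]

    def test_load_scale_invariance(self):
        """A common load factor shifts every log-stress equally and leaves
        interval profiles bit-identical (bounds are pooled quantiles)."""
        fields = synthetic_scenario_fields(seed=3)
        scaled = {
            sid: field(7.3 * f.von_mises, f.volume, f.element_id)
            for sid, f in fields.items()
        }
        a, _ = scenario_profiles(fields, IntervalConfig())
        b, _ = scenario_profiles(scaled, IntervalConfig())
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_convergence_rule_on_ladders(self):
        counts = (5, 10, 15, 25, 50)
        # identical score vectors across the ladder -> first candidate
        assert choose_interval_count(counts, [1.0, 1.0, 1.0, 1.0], 0.01) == (5, True)
        # saturating gain after the third candidate
        assert choose_interval_count(counts, [0.7, 0.9, 0.905, 0.91], 0.01) == (10, True)
        assert choose_interval_count(counts, [0.5, 0.7, 0.9, 0.905], 0.01) == (15, True)
        # monotone increase -> largest candidate, flagged non-converged
        assert choose_interval_count(counts, [0.5, 0.6, 0.7, 0.8], 0.01) == (50, False)

    def test_select_interval_count_r2_matches_correlation_oracle(self):
        fields = synthetic_scenario_fields(seed=9)
        config = IntervalConfig()
        res = select_interval_count(fields, config)
        assert res.chosen_k in config.candidate_counts
        # recompute R^2 independently from the public pipeline pieces
        from scipy import stats

        scores = []
        for k in config.candidate_counts:
            df, _ = scenario_profiles(fields, config, n_intervals=k)
            scores.append(pca_profiles(df).scores["PC1"].to_numpy())
        expected = [
            stats.pearsonr(a, b).statistic ** 2
            for a, b in zip(scores, scores[1:])
        ]
        assert np.allclose(res.r_squared_pc1, expected, atol=1e-12)
        assert all(0.0 <= r <= 1.0 for r in res.r_squared_pc1)
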