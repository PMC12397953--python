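import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bplast.entropy_arcs import (
    fit_arc_models,
    occupancy,
    peak_time,
    quadratic_vertex,
    select_model,
    shannon_entropy,
    entropy_table,
)
from bplast.metrics import IntervalSpec

IV = IntervalSpec("hour", seconds_per_hour=1.0)  # 5-frame "hours"


def _clusters(labels, individual="f1", day=1, dt=0.2):
    n = len(labels)
    return pd.DataFrame(
        {
            "individual_id": individual,
            "day_index": day,
            "time_s": dt * np.arange(n),
            "cluster": labels,
        }
    )


class TestOccupancy:
    def test_single_cluster_one_hot(self):
        occ = occupancy(_clusters([3] * 5), IV, k=5)
        np.testing.assert_array_equal(occ["probs"].iloc[0], [0, 0, 1, 0, 0])

    def test_alternating_half_half(self):
        occ = occupancy(_clusters([1, 2, 1, 2]), IV, k=2)
        np.testing.assert_allclose(occ["probs"].iloc[0], [0.5, 0.5])

    def test_counts_match_tabulation_oracle(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 21, size=18000)
        iv = IntervalSpec("hour")
        occ = occupancy(_clusters(labels), iv, k=20)
        oracle = np.bincount(labels, minlength=21)[1:]
        np.testing.assert_array_equal(occ["counts"].iloc[0], oracle)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="1..4"):
            occupancy(_clusters([1, 5]), IV, k=4)


class TestShannonEntropy:
    def test_one_hot_zero(self):
        assert shannon_entropy([0, 1.0, 0]) == 0.0

    def test_uniform_20_is_ln20(self):
        np.testing.assert_allclose(shannon_entropy(np.full(20, 0.05)), np.log(20), rtol=1e-12)

    def test_half_quarter_quarter(self):
        np.testing.assert_allclose(
            shannon_entropy([0.5, 0.25, 0.25]), 1.5 * np.log(2), rtol=1e-12
        )
        np.testing.assert_allclose(shannon_entropy([0.5, 0.25, 0.25]), 1.0397, atol=1e-4)

    def test_base_two_option(self):
        np.testing.assert_allclose(shannon_entropy([0.5, 0.25, 0.25], base=2), 1.5)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=20))
    def test_bounds_and_permutation_invariance(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        h = shannon_entropy(p)
        assert 0.0 <= h <= np.log(len(p)) + 1e-12
        rng = np.random.default_rng(0)
        assert np.isclose(h, shannon_entropy(rng.permutation(p)))

    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=12))
    def test_merging_clusters_never_increases_entropy(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        merged = np.concatenate([[p[0] + p[1]], p[2:]])
        assert shannon_entropy(merged) <= shannon_entropy(p) + 1e-12


class TestEntropyTable:
    def test_short_interval_dropped(self):
        df = _clusters([1, 2])  # 2 of 5 nominal frames
        ent = entropy_table(df, IV, k=2, min_frames_frac=0.5)
        assert len(ent) == 0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 6, size=200)
        perm = np.array([0, 3, 5, 1, 2, 4])  # permutation of 1..5
        a = entropy_table(_clusters(labels), IV, k=5)
        b = entropy_table(_clusters(perm[labels]), IV, k=5)
        np.testing.assert_allclose(a["entropy_nats"], b["entropy_nats"], rtol=1e-12)


def _simulate_response(rng, n_ind=20, n_t=100, b0=2.0, b1=0.0, b2=-0.5, sd_ri=0.3, sd_noise=0.2):
    """Quadratic fixed effect + random intercepts, on the standardized axis."""
    t = np.tile(np.arange(1, n_t + 1), n_ind).astype(float)
    z = (t - t.mean()) / t.std()
    ind = np.repeat([f"i{j:02d}" for j in range(n_ind)], n_t)
    ri = dict(zip(sorted(set(ind)), rng.normal(0, sd_ri, n_ind)))
    y = b0 + b1 * z + b2 * z**2 + np.array([ri[i] for i in ind]) + rng.normal(0, sd_noise, len(t))
    return pd.DataFrame(
        {"individual_id": ind, "interval_index": t.astype(int), "entropy_nats": y}
    )


class TestArcModels:
    def test_quadratic_parameter_recovery(self):
        rng = np.random.default_rng(0)
        df = _simulate_response(rng, b2=-0.5)
        fit = fit_arc_models(df, "entropy_nats", "quadratic", IntervalSpec("hour"), covariates=False)
        se = 0.05  # generous bound: |beta2_hat - beta2| within 3 nominal SEs
        assert abs(fit.beta2 - (-0.5)) < 3 * se
        assert fit.aic < np.inf and np.isfinite(fit.bic)

    def test_constant_response_gives_null_coefficients(self):
        n_ind, n_t = 8, 30
        df = pd.DataFrame(
            {
                "individual_id": np.repeat([f"i{j}" for j in range(n_ind)], n_t),
                "interval_index": np.tile(np.arange(1, n_t + 1), n_ind),
                "entropy_nats": 1.234,
            }
        )
        fit = fit_arc_models(df, "entropy_nats", "quadratic", IntervalSpec("hour"), covariates=False)
        assert abs(fit.beta1) < 1e-6 and abs(fit.beta2) < 1e-6

    def test_quadratic_on_linear_truth_covers_zero(self):
        """The 95% beta2 CI covers 0 in >= 90% of simulations from linear truth."""
        rng = np.random.default_rng(7)
        cover = 0
        n_sim = 25
        for _ in range(n_sim):
            df = _simulate_response(rng, n_ind=12, n_t=50, b1=0.4, b2=0.0)
            fit = fit_arc_models(df, "entropy_nats", "quadratic", IntervalSpec("hour"), covariates=False)
            cover += abs(fit.beta2) < 1.96 * fit.bse["_z2"]
        assert cover >= 0.9 * n_sim

    def test_too_few_individuals_rejected(self):
        rng = np.random.default_rng(1)
        df = _simulate_response(rng, n_ind=3)
        with pytest.raises(ValueError, match="5 individuals"):
            fit_arc_models(df, "entropy_nats", "quadratic", IntervalSpec("hour"))


class TestSelection:
    def _fits(self, rng, b2):
        df = _simulate_response(rng, n_ind=15, n_t=60, b1=0.3, b2=b2)
        iv = IntervalSpec("hour")
        lin = fit_arc_models(df, "entropy_nats", "linear", iv, covariates=False)
        quad = fit_arc_models(df, "entropy_nats", "quadratic", iv, covariates=False)
        return lin, quad, df

    def test_strong_inverted_u_quadratic_wins_both(self):
        lin, quad, _ = self._fits(np.random.default_rng(0), b2=-0.6)
        sel = select_model(lin, quad)
        assert sel.winner_aic == "quadratic" and sel.winner_bic == "quadratic"

    def test_pure_linear_trend_linear_wins_bic(self):
        lin, quad, _ = self._fits(np.random.default_rng(1), b2=0.0)
        sel = select_model(lin, quad)
        assert sel.winner_bic == "linear"

    def test_identical_fits_tie_flagged(self):
        lin, quad, _ = self._fits(np.random.default_rng(2), b2=-0.6)
        sel = select_model(quad, quad)
        assert sel.tie and sel.delta_aic == 0


class TestPeak:
    def test_vertex_formula_135(self):
        np.testing.assert_allclose(quadratic_vertex(2.7, -0.01), 135.0)

    def test_zero_slope_vertex_zero(self):
        assert quadratic_vertex(0.0, -1.0) == 0.0

    def test_convex_fit_reports_no_peak(self):
        rng = np.random.default_rng(3)
        df = _simulate_response(rng, b2=+0.5)
        fit = fit_arc_models(df, "entropy_nats", "quadratic", IntervalSpec("hour"), covariates=False)
        est = peak_time(fit, df, IntervalSpec("hour"), n_boot=10)
        assert est.peak_hour is None

    def test_bootstrap_ci_brackets_programmed_peak(self):
        rng = np.random.default_rng(4)
        # vertex at z* = -b1/(2 b2) = 0.5 on the standardized axis
        df = _simulate_response(rng, n_ind=25, b1=0.5, b2=-0.5)
        iv = IntervalSpec("hour")
        fit = fit_arc_models(df, "entropy_nats", "quadratic", iv, covariates=False)
        est = peak_time(fit, df, iv, n_boot=200, seed=0)
        t = np.arange(1, 101)
        true_peak = t.mean() + t.std() * 0.5
        assert est.ci_low < true_peak < est.ci_high
        assert abs(est.peak_hour - true_peak) < 5
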