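"""Observed-vs-forecast validation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from exmort import (
    build_matrix,
    combine,
    euclidean_distance,
    fit_forecaster,
    generate_panel,
    validate_windows,
    wilcoxon_rank_sum,
    windowed_estimates,
)
from exmort.errors import ExmortError

from conftest import make_config


def mann_whitney_oracle(x, y):
    """Direct pair count: #(x_i > y_j) + half of #(x_i == y_j)."""
    w = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                w += 1.0
            elif xi == yj:
                w += 0.5
    return w


def combined_matrix(n_obs=194, horizon=104, seed=3):
    config = make_config(n_weeks=n_obs, seed=seed)
    panel = generate_panel(config)
    model = fit_forecaster(panel)
    return build_matrix(combine(panel, model.forecast(horizon)))


class TestWindows:
    def test_window_row_counts_for_study_shape(self):
        matrix = combined_matrix()
        seg = matrix.segments
        assert (seg == "observed").sum() == 193
        assert (seg == "forecast").sum() == 103
        assert (seg == "boundary").sum() == 1
        assert matrix.n == 297

    def test_boundary_toggle_changes_forecast_window(self):
        matrix = combined_matrix()
        excl = windowed_estimates(matrix, include_boundary=False)
        incl = windowed_estimates(matrix, include_boundary=True)
        # weights differ: 103 vs 104 rows in the forecast window
        n_fc = (matrix.segments == "forecast").sum()
        assert np.allclose(
            incl["p_hat_forecast"] * (n_fc + 1) - excl["p_hat_forecast"] * n_fc,
            matrix.indicators[matrix.segments == "boundary"][0],
        )

    def test_all_ones_forecast_segment(self):
        matrix = combined_matrix()
        matrix.indicators[matrix.segments == "forecast"] = 1
        est = windowed_estimates(matrix)
        assert (est["p_hat_forecast"] == 1.0).all()

    def test_stationary_panel_windows_agree(self):
        """Stationary generator: observed and forecast windows should give
        similar p-hats in at least 90% of seeded replicates (two-proportion
        95% bound)."""
        from scipy import stats

        hits = trials = 0
        for seed in range(40):
            matrix = combined_matrix(n_obs=150, horizon=80, seed=seed)
            est = windowed_estimates(matrix)
            n1 = (matrix.segments == "observed").sum()
            n2 = (matrix.segments == "forecast").sum()
            for _, row in est.iterrows():
                p_pool = (row["p_hat_observed"] * n1 + row["p_hat_forecast"] * n2) / (
                    n1 + n2
                )
                se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
                hits += row["abs_diff"] <= stats.norm.ppf(0.975) * se
                trials += 1
        assert hits / trials >= 0.90


class TestEuclidean:
    def test_identical_vectors(self):
        assert euclidean_distance([0.1, 0.2], [0.1, 0.2]) == 0.0

    def test_single_unit_coordinate(self):
        assert euclidean_distance([0.0, 1.0, 0.0], [0.0, 0.0, 0.0]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ExmortError, match="mismatch"):
            euclidean_distance([0.1], [0.1, 0.2])

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            x, y, z = rng.random((3, 14))
            assert euclidean_distance(x, y) == pytest.approx(euclidean_distance(y, x))
            assert euclidean_distance(x, z) <= (
                euclidean_distance(x, y) + euclidean_distance(y, z) + 1e-12
            )


class TestWilcoxon:
    def test_identical_samples_half_pairs(self):
        x = np.arange(14.0)
        w, _ = wilcoxon_rank_sum(x, x)
        assert w == 14 * 14 / 2  # 98: every pair is a tie, half each

    def test_fully_separated_samples(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert w == 0.0
        assert 0.0 < p < 1.0

    def test_statistic_matches_pair_count_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            x = np.round(rng.random(9), 1)  # coarse grid forces ties
            y = np.round(rng.random(7), 1)
            w, _ = wilcoxon_rank_sum(x, y)
            assert w == pytest.approx(mann_whitney_oracle(x, y), abs=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(29)
        x, y = rng.random(14), rng.random(14)
        wxy, _ = wilcoxon_rank_sum(x, y)
        wyx, _ = wilcoxon_rank_sum(y, x)
        assert wxy + wyx == pytest.approx(14 * 14, abs=1e-9)

    def test_small_sample_p_agrees_with_permutation_enumeration(self):
        """Exhaustive relabelling gives the exact two-sided p; the normal
        approximation should be in its stated regime (same order, same
        accept/reject at 5%) even at n = 4 + 4."""
        x = np.array([0.9, 1.4, 2.1, 2.5])
        y = np.array([0.3, 0.6, 1.1, 1.8])
        w_obs, p_normal = wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        n1 = len(x)
        dev_obs = abs(mann_whitney_oracle(x, y) - n1 * len(y) / 2)
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            dev = abs(mann_whitney_oracle(xs, ys) - n1 * len(ys) / 2)
            count += dev >= dev_obs - 1e-9
            total += 1
        p_exact = count / total
        assert (p_normal < 0.05) == (p_exact < 0.05)
        assert abs(p_normal - p_exact) < 0.1


class TestReport:
    def test_report_round_trip_and_verdict(self, tmp_path):
        matrix = combined_matrix()
        report = validate_windows(matrix)
        d = report.to_dict()
        assert set(d["p_hat"]) == set(matrix.cause_labels)
        assert d["window"]["observed_rows"] == 193
        assert "significant" in report.verdict
        report.to_csv(tmp_path / "table.csv")
        back = pd.read_csv(tmp_path / "table.csv")
        assert list(back.columns) == ["p_hat", "observed", "forecast", "abs_diff"]
        assert len(back) == len(matrix.cause_labels)
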