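"""Mann-Whitney machinery, effect size, network and baseline comparison."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allonet import (
    baseline_compare,
    compare_networks,
    compute_all_metrics,
    effect_size_r,
    format_comparison,
    mann_whitney_u,
)

from brute import mwu_exact_p_oracle, mwu_u_oracle


class TestMannWhitneyU:
    def test_complete_separation_exact(self):
        """Only the two extreme assignments of 6 values reach |U - mu| = 4.5."""
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.exact
        assert res.p == pytest.approx(2 / 20, abs=1e-12)

    def test_interleaved_pair_count(self):
        res = mann_whitney_u([1, 3], [2, 4])
        assert res.U == 1.0

    def test_identical_samples(self):
        x = [1.0, 2.0, 2.0, 3.0]
        res = mann_whitney_u(x, x)
        assert res.U == len(x) ** 2 / 2
        assert res.Z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_u_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(2, 15, size=2)
            x = rng.integers(0, 8, n1).astype(float)
            y = rng.integers(0, 8, n2).astype(float)
            res = mann_whitney_u(x, y)
            assert res.U == pytest.approx(mwu_u_oracle(x, y), abs=1e-9)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 13 - n1 - 1))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney_u(x, y)
            assert res.exact
            assert res.p == pytest.approx(mwu_exact_p_oracle(x, y), abs=1e-12)

    def test_exact_vs_normal_approximation(self, rng):
        """Normal-approximation p within 0.08 of exact for pooled n <= 12."""
        for _ in range(25):
            n1 = int(rng.integers(3, 7))
            n2 = int(rng.integers(3, 13 - n1))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            p_exact = mann_whitney_u(x, y).p
            p_norm = mann_whitney_u(x, y, exact_threshold=0).p
            assert abs(p_exact - p_norm) < 0.08

    def test_matches_scipy_asymptotic(self, rng):
        for _ in range(50):
            x = rng.integers(0, 6, int(rng.integers(8, 25))).astype(float)
            y = rng.integers(0, 6, int(rng.integers(8, 25))).astype(float)
            res = mann_whitney_u(x, y, exact_threshold=0)
            ref = stats.mannwhitneyu(
                x, y, method="asymptotic", use_continuity=True, alternative="two-sided"
            )
            assert res.U == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=14)
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(y, x)
        assert a.U + b.U == pytest.approx(10 * 14)
        assert a.Z == pytest.approx(-b.Z)
        assert a.p == pytest.approx(b.p)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestEffectSize:
    def test_zero(self):
        assert effect_size_r(0.0, 10) == 0.0

    def test_magnitude(self):
        assert effect_size_r(2.0, 16) == pytest.approx(0.5)

    def test_signed_direction(self):
        assert effect_size_r(1.1, 25, direction=-1) == pytest.approx(-0.22)
        assert effect_size_r(-1.1, 25, direction=1) == pytest.approx(0.22)

    def test_clipping_logged(self, caplog):
        with caplog.at_level("WARNING"):
            r = effect_size_r(10.0, 4)
        assert r == 1.0
        assert caplog.records


class TestCompareNetworks:
    def path_star_metrics(self):
        path = compute_all_metrics(nx.path_graph(21))
        star = compute_all_metrics(nx.star_graph(20))
        return path, star

    def test_identical_tables_full_ties(self):
        m = compute_all_metrics(nx.path_graph(21))
        report = compare_networks(m, m)
        assert np.allclose(report.table["p"], 1.0)
        assert (report.table["r"] == 0.0).all()
        assert (report.table["direction"] == "tie").all()

    def test_path_vs_star_eccentricity(self):
        """A 21-chain is metrically elongated; the star is compact."""
        path, star = self.path_star_metrics()
        report = compare_networks(path, star)
        row = report.table.loc["eccentricity"]
        assert row.p < 0.001
        assert row.direction == "A higher"
        assert row.r > 0

    def test_antisymmetry_of_report(self):
        path, star = self.path_star_metrics()
        ab = compare_networks(path, star).table
        ba = compare_networks(star, path).table
        for m in ab.index:
            assert ab.loc[m, "U"] + ba.loc[m, "U"] == pytest.approx(21 * 21)
            assert ab.loc[m, "r"] == pytest.approx(-ba.loc[m, "r"], abs=1e-12)

    def test_missing_metric_rejected(self):
        path, star = self.path_star_metrics()
        with pytest.raises(KeyError):
            compare_networks(path.drop(columns=["stress"]), star)

    def test_non_isolated_policy_drops_degree_zero(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2)])
        g.add_nodes_from([3, 4])
        m = compute_all_metrics(g)
        full = compare_networks(m, m)
        trimmed = compare_networks(m, m, include_isolated=False)
        assert full.table["n1"].iloc[0] == 5
        assert trimmed.table["n1"].iloc[0] == 3
        assert trimmed.metadata["node_inclusion"] == "non-isolated"

    def test_format_matches_reporting_style(self):
        path, star = self.path_star_metrics()
        text = format_comparison(compare_networks(path, star))
        assert "vs." in text and "p = " in text and "r = " in text


class TestTypeICalibration:
    def test_mwu_calibrated_on_independent_draws(self, rng):
        """At alpha 0.05, iid zero-inflated samples reject ~5%."""
        rejections = 0
        trials = 800
        for _ in range(trials):
            x = rng.poisson(0.7, 21).astype(float) * rng.integers(0, 3, 21)
            y = rng.poisson(0.7, 21).astype(float) * rng.integers(0, 3, 21)
            if mann_whitney_u(x, y).p < 0.05:
                rejections += 1
        assert 0.02 < rejections / trials < 0.08

    def test_network_vectors_inflate_rejection(self, rng):
        """Dependent node values within a network genuinely inflate the
        network-comparison rejection rate above nominal — the procedure's
        documented caveat, reproduced rather than hidden."""
        from allonet import build_network, default_panel, generate_cohort, spearman_matrix
        from allonet.cohort import CohortSpec
        from dataclasses import replace

        panel = default_panel()
        spec = CohortSpec(panel=panel, n_per_group=(32, 18))
        rejections = 0
        trials = 120
        for s in range(trials):
            before, _ = generate_cohort(replace(spec, seed=31000 + s))
            tables = {}
            for g in ("A", "B"):
                corr = spearman_matrix(before[before.group == g], panel)
                tables[g] = compute_all_metrics(build_network(corr, 0.05, panel))
            if compare_networks(tables["A"], tables["B"]).table.loc["stress", "p"] < 0.05:
                rejections += 1
        assert rejections / trials > 0.05  # inflated above nominal


class TestBaselineCompare:
    def frame(self, values, var="x"):
        return pd.DataFrame({var: values})

    def test_normal_equal_routed_to_ttest(self, rng):
        a = self.frame(rng.normal(0, 1, 200))
        b = self.frame(rng.normal(0, 1, 200))
        report = baseline_compare(a, b, ["x"])
        row = report.loc["x"]
        assert row.test == "t-test"
        assert row.normal_a and row.normal_b and row.equal_var
        assert row.p > 0.001

    def test_skewed_routed_to_mann_whitney(self, rng):
        a = self.frame(np.exp(rng.normal(0, 1, 150)))
        b = self.frame(np.exp(rng.normal(0, 1, 150)))
        report = baseline_compare(a, b, ["x"])
        row = report.loc["x"]
        assert row.test == "mann-whitney"
        assert not (row.normal_a and row.normal_b)

    def test_identical_groups_consistent(self, rng):
        vals = rng.normal(0, 1, 50)
        report = baseline_compare(self.frame(vals), self.frame(vals), ["x"])
        row = report.loc["x"]
        assert row.p > 0.5
        if row.test == "t-test":
            assert row.normal_a and row.normal_b and row.equal_var
        else:
            assert not (row.normal_a and row.normal_b and row.equal_var)

    def test_insufficient_data_reported_not_raised(self, rng):
        a = pd.DataFrame({"x": [1.0, 2.0], "y": rng.normal(size=2)})
        b = pd.DataFrame({"x": rng.normal(size=10), "y": rng.normal(size=10)})
        report = baseline_compare(a, b, ["x", "y"])
        assert (report["test"] == "insufficient").all()
        assert report["p"].isna().all()
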