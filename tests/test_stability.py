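"""Summaries, paired comparisons, clustering and subsampling of ICC tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from methstab import stability
from methstab.config import GroupSpec, SimConfig, StressSpec
from methstab.scenarios import SCENARIOS
from methstab.simulate import generate_cohort


class TestSummarize:
    def test_constant_vector(self):
        s = stability.summarize(np.full(100, 0.5))
        assert s.mean == s.median == 0.5
        assert s.sd == 0.0 and s.skewness == 0.0 and s.excess_kurtosis == 0.0

    def test_exclusion_rule(self):
        s = stability.summarize([0.005, 0.5, 0.7])
        assert s.n_included == 2 and s.n_excluded_low == 1
        assert s.mean == pytest.approx(0.6)

    def test_exactly_threshold_included(self):
        s = stability.summarize([0.01, 0.5])
        assert s.n_included == 2

    def test_counts_partition_total(self):
        v = np.random.default_rng(0).random(500)
        s = stability.summarize(v)
        assert s.n_included + s.n_excluded_low == 500

    def test_moments_match_textbook_formulas(self):
        """Bias-corrected G1/G2 recomputed from raw sums on a fixed vector."""
        rng = np.random.default_rng(4)
        v = np.round(rng.uniform(0.05, 0.95, 20), 3)
        s = stability.summarize(v)
        n = len(v)
        m = v.mean()
        m2 = ((v - m) ** 2).mean()
        m3 = ((v - m) ** 3).mean()
        m4 = ((v - m) ** 4).mean()
        g1 = m3 / m2**1.5
        G1 = g1 * np.sqrt(n * (n - 1)) / (n - 2)
        g2 = m4 / m2**2 - 3
        G2 = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
        assert s.skewness == pytest.approx(G1, abs=1e-12)
        assert s.excess_kurtosis == pytest.approx(G2, abs=1e-12)
        assert s.sd == pytest.approx(v.std(ddof=1), abs=1e-12)

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            stability.summarize([0.001, 0.002])


class TestBins:
    def test_one_probe_per_bin(self):
        bins = stability.bin_probes([0.0, 0.3, 0.6, 0.8, 0.95])
        assert bins["count"].tolist() == [1, 1, 1, 1, 1]

    def test_all_zeros_in_lowest(self):
        bins = stability.bin_probes(np.zeros(10))
        assert bins["percent"].tolist()[0] == 100.0

    def test_boundary_rules(self):
        """0.01 goes to the second bin; 0.90 to the fourth; >0.90 to the last."""
        bins = stability.bin_probes([0.009999, 0.01, 0.5, 0.75, 0.90, 0.900001])
        assert bins["count"].tolist() == [1, 1, 1, 1, 2]

    def test_percentages_sum_to_100(self):
        v = np.random.default_rng(1).random(777)
        assert stability.bin_probes(v)["percent"].sum() == pytest.approx(100.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stability.bin_probes([1.2])


class TestComparePaired:
    def test_identical_vectors(self):
        v = np.linspace(0.1, 0.9, 10)
        assert stability.compare_paired(v, v) == (0.0, 1.0)

    def test_constant_offset(self):
        v = np.linspace(0.1, 0.8, 10)
        beta, p = stability.compare_paired(v, v + 0.1)
        assert beta == pytest.approx(-0.1)
        assert p < 1e-50

    def test_matches_hand_computed_t(self):
        a = np.array([0.5, 0.6, 0.4, 0.7, 0.55, 0.62, 0.48, 0.51, 0.66, 0.43])
        b = np.array([0.45, 0.63, 0.35, 0.72, 0.5, 0.58, 0.4, 0.52, 0.6, 0.41])
        beta, p = stability.compare_paired(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats

        assert beta == pytest.approx(d.mean())
        assert p == pytest.approx(2 * stats.t.sf(abs(t), len(d) - 1), abs=1e-12)

    def test_antisymmetric(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(30), rng.random(30)
        beta_ab, p_ab = stability.compare_paired(a, b)
        beta_ba, p_ba = stability.compare_paired(b, a)
        assert beta_ab == pytest.approx(-beta_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            stability.compare_paired([0.5], [0.6])


class TestLowICCChisq:
    def test_identical_counts(self):
        stat, p = stability.low_icc_chisq((100, 900), (100, 900))
        assert stat == 0.0 and p == 1.0

    def test_matches_hand_formula(self):
        stat, p = stability.low_icc_chisq((100, 900), (200, 800))
        obs = np.array([[100, 900], [200, 800]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum())
        assert 0 < p < 1

    def test_extreme_imbalance_tiny_p(self):
        _, p = stability.low_icc_chisq((500, 500), (0, 1000))
        assert p < 1e-10

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            stability.low_icc_chisq((0, 0), (1, 1))


def _long_table(data: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for scen, vals in data.items():
        for i, v in enumerate(vals):
            rows.append((f"p{i:05d}", scen, float(v), float(v), True, True))
    return pd.DataFrame(
        rows, columns=["probe_id", "scenario", "icc21", "icc2k", "adjusted", "converged"]
    )


class TestScenarioCorrelations:
    def test_identical_tables(self):
        v = np.linspace(0.1, 0.9, 50)
        out = stability.scenario_correlations(_long_table({"A": v, "B": v}))
        assert np.allclose(out.to_numpy(), 1.0)

    def test_independent_tables_near_zero(self):
        rng = np.random.default_rng(6)
        out = stability.scenario_correlations(
            _long_table({"A": rng.random(10_000), "B": rng.random(10_000)})
        )
        assert abs(out.loc["A", "B"]) < 0.05

    def test_matches_formula_on_fixture(self):
        a = np.array([0.2, 0.4, 0.6, 0.8, 0.5])
        b = np.array([0.3, 0.35, 0.7, 0.75, 0.45])
        out = stability.scenario_correlations(_long_table({"A": a, "B": b}))
        r = np.corrcoef(a, b)[0, 1]
        assert out.loc["A", "B"] == pytest.approx(r, abs=1e-12)

    def test_pairwise_exclusion(self):
        """A probe below 0.01 in either scenario is dropped from that pair."""
        a = np.array([0.005, 0.4, 0.6, 0.8])
        b = np.array([0.3, 0.35, 0.7, 0.75])
        out = stability.scenario_correlations(_long_table({"A": a, "B": b}))
        r = np.corrcoef(a[1:], b[1:])[0, 1]
        assert out.loc["A", "B"] == pytest.approx(r, abs=1e-12)


class TestClustering:
    def test_identical_scenarios_merge_at_zero(self):
        v = np.linspace(0.1, 0.9, 20)
        Z, labels = stability.cluster_scenarios(_long_table({"A": v, "B": v, "C": v + 0.2}))
        assert Z[0, 2] == pytest.approx(0.0)

    def test_complete_linkage_hand_trace(self):
        """Scenario vectors at mutual distances 1, 2, ~2.24: A,B merge at 1,
        then C joins at the maximum distance to the pair."""
        tab = _long_table(
            {
                "A": np.array([0.5, 0.5]),
                "B": np.array([0.5 + 1 / np.sqrt(2), 0.5 + 1 / np.sqrt(2)]),
                "C": np.array([0.5, 0.5 + 2.0]),
            }
        )
        Z, labels = stability.cluster_scenarios(tab)
        d_ab = 1.0
        d_ac = 2.0
        d_bc = np.sqrt((1 / np.sqrt(2)) ** 2 + (2 - 1 / np.sqrt(2)) ** 2)
        assert Z[0, 2] == pytest.approx(d_ab)
        assert Z[1, 2] == pytest.approx(max(d_ac, d_bc))

    def test_order_invariance_up_to_isomorphism(self, small_icc_tables):
        tab = small_icc_tables
        rev = tab.iloc[::-1].reset_index(drop=True)
        Z1, l1 = stability.cluster_scenarios(tab)
        Z2, l2 = stability.cluster_scenarios(rev)
        assert sorted(Z1[:, 2]) == pytest.approx(sorted(Z2[:, 2]))

    def test_newick_rendering_parses(self, small_icc_tables):
        Z, labels = stability.cluster_scenarios(small_icc_tables)
        nwk = stability.linkage_to_newick(Z, labels)
        assert nwk.endswith(";")
        for lab in labels:
            assert lab in nwk

    def test_stress_scenarios_form_a_clade(self):
        """When stress stabilizes probes, Stress scenarios cluster together."""
        rng = np.random.default_rng(9)
        base = rng.random(3000)
        data = {}
        for s in ("NoStressT1-2", "NoStressT1-4", "CrossSessionT1"):
            data[s] = np.clip(base + rng.normal(0, 0.05, 3000), 0.02, 1)
        for s in ("StressT1-2", "StressT1-4"):
            data[s] = np.clip(base + 0.3 + rng.normal(0, 0.05, 3000), 0.02, 1)
        Z, labels = stability.cluster_scenarios(_long_table(data))
        leaves = hierarchy.fcluster(Z, t=2, criterion="maxclust")
        groups = {}
        for lab, cl in zip(labels, leaves):
            groups.setdefault(cl, set()).add(lab)
        assert {"StressT1-2", "StressT1-4"} in groups.values()


class TestSubsample:
    def test_full_sample_equals_full_table(self, small_cohort):
        c = small_cohort
        sc = SCENARIOS["StressT1-2"]
        n_all = c.sheet["subject_id"].nunique()
        full = stability.subsample_icc(c.beta.iloc[:10], c.sheet, sc, n_sub=n_all, seed=1)
        from methstab.icc import compute_scenario_icc

        ref = compute_scenario_icc(c.beta.iloc[:10], c.sheet, sc)
        pd.testing.assert_frame_equal(full, ref)

    def test_seed_reproducibility(self, small_cohort):
        c = small_cohort
        sc = SCENARIOS["StressT1-2"]
        a = stability.subsample_icc(c.beta.iloc[:8], c.sheet, sc, n_sub=10, seed=42)
        b = stability.subsample_icc(c.beta.iloc[:8], c.sheet, sc, n_sub=10, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_subsample_rejected(self, small_cohort):
        c = small_cohort
        with pytest.raises(ValueError):
            stability.subsample_icc(c.beta, c.sheet, SCENARIOS["StressT1-2"], n_sub=999)


class TestStratify:
    def test_matched_groups_show_no_difference(self):
        cfg = SimConfig(
            n_subjects_per_group=8,
            n_probes=40,
            group_spec=GroupSpec(ela_resid_multiplier=1.0),
            stress_spec=StressSpec(n_responsive=0),
            seed=13,
        )
        c = generate_cohort(cfg)
        _, comparison = stability.stratify_by_group(
            c.beta, c.sheet, SCENARIOS["StressT1-2"]
        )
        assert abs(comparison["beta"]) < 0.08

    def test_single_subject_group_rejected(self, small_cohort):
        c = small_cohort
        sheet = c.sheet[
            (c.sheet["group"] == "control") | (c.sheet["subject_id"] == "sub009")
        ]
        with pytest.raises(ValueError, match="fewer than 2"):
            stability.stratify_by_group(c.beta, sheet, SCENARIOS["StressT1-2"])
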