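import numpy as np
import pandas as pd
import pytest

import riskdrift as rd
from riskdrift.popstats import kimura_ohta_age

from test_panel import make_record


class TestPairedWilcoxon:
    def test_all_positive_differences_exact_p(self):
        # oracle: enumeration of all 2^6 sign assignments; the observed
        # statistic is the extreme in both tails -> p = 2/64
        afr = np.array([0.5, 0.6, 0.7, 0.4, 0.8, 0.55])
        non_afr = afr - np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        res = rd.paired_wilcoxon_frequency_test(afr, non_afr)
        assert res.pvalue == pytest.approx(2 / 64)

    def test_symmetric_differences_not_significant(self):
        afr = np.array([0.5, 0.5, 0.5, 0.5])
        non_afr = afr + np.array([0.1, -0.1, 0.2, -0.2])
        assert rd.paired_wilcoxon_frequency_test(afr, non_afr).pvalue == pytest.approx(1.0)

    def test_scale_invariance_of_p(self):
        afr = np.array([0.5, 0.62, 0.41, 0.77, 0.3])
        non_afr = np.array([0.45, 0.60, 0.52, 0.70, 0.35])
        p1 = rd.paired_wilcoxon_frequency_test(afr, non_afr).pvalue
        d = (afr - non_afr) * 3.7
        p2 = rd.paired_wilcoxon_frequency_test(non_afr + d, non_afr).pvalue
        assert p1 == pytest.approx(p2)

    def test_all_zero_differences_is_error(self):
        with pytest.raises(ValueError):
            rd.paired_wilcoxon_frequency_test([0.5, 0.5], [0.5, 0.5])

    def test_matches_enumeration_for_small_n(self):
        # independent oracle: full enumeration of sign flips for the
        # signed-rank statistic (no ties, n <= 8)
        from itertools import product

        rng = np.random.default_rng(0)
        d = rng.normal(0.02, 0.05, size=7)
        ranks = pd.Series(np.abs(d)).rank().to_numpy()
        w_plus = ranks[d > 0].sum()
        null = [np.sum(ranks[list(signs)]) for signs in product([False, True], repeat=7)]
        null = np.array(null)
        p_exact = min(1.0, 2 * min((null <= w_plus).mean(), (null >= w_plus).mean()))
        res = rd.paired_wilcoxon_frequency_test(d + 1.0, np.ones_like(d))
        assert res.pvalue == pytest.approx(p_exact)


class TestStateDifferences:
    def make_panel(self, rows):
        records = []
        for i, daf in enumerate(rows):
            records.append(make_record(id=f"L{i}", pos=i + 1, daf=dict(zip(rd.POPULATIONS, daf))))
        return rd.Panel.from_records(records)

    def test_identical_frequencies_give_zero_deltas_and_ties(self):
        panel = self.make_panel([[0.3] * 5, [0.6] * 5])
        table = pd.DataFrame({"id": ["L0", "L1"], "risk_state": ["ancestral", "derived"],
                              "category": "cancer"})
        d = rd.frequency_difference_by_state(table, panel)
        assert d.delta_ancestral == 0.0 and d.delta_derived == 0.0
        assert d.frac_higher_afr_ancestral == 0.0  # ties are not-higher
        assert d.ties_ancestral == 1 and d.ties_derived == 1

    def test_mean_difference_arithmetic(self):
        # ancestral risk freq = 1 - daf: choose dafs so risk freqs are
        # AFR (0.8, 0.5) vs non-AFR (0.6, 0.6)
        panel = self.make_panel([
            [0.2, 0.4, 0.4, 0.4, 0.4],
            [0.5, 0.4, 0.4, 0.4, 0.4],
        ])
        table = pd.DataFrame({"id": ["L0", "L1"], "risk_state": "ancestral",
                              "category": "cancer"})
        d = rd.frequency_difference_by_state(table, panel)
        assert d.delta_ancestral == pytest.approx(0.05)
        assert d.frac_higher_afr_ancestral == pytest.approx(0.5)

    def test_antisymmetric_under_population_swap(self):
        rng = np.random.default_rng(1)
        rows = rng.random((20, 5))
        swapped = rows.copy()
        swapped[:, 0] = rows[:, 1:].mean(axis=1)
        # replace all non-AFR columns by the original AFR value
        swapped[:, 1:] = rows[:, [0]]
        panel_a, panel_b = self.make_panel(rows), self.make_panel(swapped)
        table = pd.DataFrame({"id": [f"L{i}" for i in range(20)],
                              "risk_state": ["derived"] * 20, "category": "cancer"})
        da = rd.frequency_difference_by_state(table, panel_a)
        db = rd.frequency_difference_by_state(table, panel_b)
        assert da.delta_derived == pytest.approx(-db.delta_derived)

    def test_unjoinable_ids_error(self, small_panel):
        table = pd.DataFrame({"id": ["missing"], "risk_state": ["derived"], "category": "cancer"})
        with pytest.raises(ValueError, match="missing"):
            rd.frequency_difference_by_state(table, small_panel)


class TestWeightedDifference:
    def test_equal_deltas_collapse(self):
        assert rd.overall_weighted_difference(0.07, 0.07, 0.3) == pytest.approx(0.07)

    def test_printed_inputs_reproduce_printed_output(self):
        # two-decimal printed inputs give +1.16; the source's unrounded
        # inputs give +1.15 — both consistent within input rounding
        val = rd.overall_weighted_difference(9.51, -5.40, 0.44)
        assert round(val, 2) == 1.16
        assert abs(val - 1.15) < 0.02

    def test_degenerate_proportions(self):
        assert rd.overall_weighted_difference(1.0, -2.0, 0.0) == -2.0
        assert rd.overall_weighted_difference(1.0, -2.0, 1.0) == 1.0


class TestDafBins:
    def make_inputs(self, mean_dafs, states=None):
        records = [
            make_record(id=f"L{i}", pos=i + 1, daf={p: m for p in rd.POPULATIONS})
            for i, m in enumerate(mean_dafs)
        ]
        panel = rd.Panel.from_records(records)
        states = states or ["derived"] * len(mean_dafs)
        table = pd.DataFrame({"id": [f"L{i}" for i in range(len(mean_dafs))],
                              "risk_state": states, "category": "cancer"})
        return table, panel

    def test_boundary_value_falls_in_lower_bin(self):
        # lowest bin is closed [0, 0.2]; 0.2 belongs to it
        table, panel = self.make_inputs([0.2])
        out = rd.daf_bin_differences(table, panel)
        populated = out[out["n_loci"] > 0]
        assert len(populated) == 1
        assert populated.iloc[0]["bin_low"] == 0.0
        assert populated.iloc[0]["bin_high"] == pytest.approx(0.2)

    def test_single_populated_bin_when_all_rare(self):
        table, panel = self.make_inputs([0.05, 0.1, 0.15])
        out = rd.daf_bin_differences(table, panel)
        assert (out["n_loci"] > 0).sum() == 1

    def test_low_daf_bin_has_least_bias_for_discovered_loci(self, demo_panel):
        # drift variance f*p0*(1-p0) vanishes for young (low-DAF) alleles, so
        # catalogs discovered in a EUR cohort show the least AFR-vs-non-AFR
        # bias in the lowest DAF bin; averaged over 3 simulated catalogs
        per_bin = []
        for i in range(3):
            cfg = rd.SimConfig(platform="WGS", study_pop="EUR", risk_state="ancestral",
                               n_target=2000, seed=2)
            rep = rd.rejection_sample_associations(
                demo_panel, cfg, rng=np.random.default_rng([2, i]))
            table = pd.DataFrame({"id": rep.loci["id"], "risk_state": "ancestral",
                                  "category": "cancer"})
            out = rd.daf_bin_differences(table, demo_panel)
            sub = out[(out["risk_state"] == "ancestral") & (out["n_loci"] > 30)]
            per_bin.append(sub.set_index("bin_low")["delta_afr_nonafr"])
        avg = pd.concat(per_bin, axis=1).abs().mean(axis=1)
        assert (avg.loc[0.0] < avg.loc[avg.index > 0.1]).all()


class TestAlleleAge:
    def test_reference_values(self):
        assert rd.allele_age(0.2, N=10_000, gen_time=25.0) == pytest.approx(125_000)
        assert rd.allele_age(0.5, N=10_000, gen_time=25.0) == pytest.approx(500_000)

    def test_vanishes_for_young_alleles(self):
        assert rd.allele_age(1e-9) < 1.0

    def test_strictly_increasing_in_frequency(self):
        ps = np.linspace(0.01, 0.99, 50)
        ages = [rd.allele_age(p) for p in ps]
        assert all(a < b for a, b in zip(ages, ages[1:]))

    def test_out_of_range_frequency_raises(self):
        for p in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                rd.allele_age(p)

    def test_pluggable_alternative_formula(self):
        age = rd.allele_age(0.2, N=10_000, gen_time=25.0, formula=kimura_ohta_age)
        assert age == pytest.approx(-4 * 10_000 * 0.2 * np.log(0.2) / 0.8 * 25)


class TestCategoryCorrelation:
    def test_collinear_points_give_r2_one(self):
        s = pd.DataFrame({"prop_ancestral": [0.1, 0.5, 0.9],
                          "delta_afr_nonafr": [0.01, 0.05, 0.09]})
        assert rd.category_correlation(s) == pytest.approx(1.0)

    def test_constant_delta_is_error(self):
        s = pd.DataFrame({"prop_ancestral": [0.1, 0.5, 0.9],
                          "delta_afr_nonafr": [0.03, 0.03, 0.03]})
        with pytest.raises(ValueError):
            rd.category_correlation(s)

    def test_seven_point_fixture_matches_pearson_formula(self):
        x = np.array([0.30, 0.45, 0.50, 0.55, 0.60, 0.35, 0.25])
        y = np.array([-0.01, 0.02, 0.03, 0.05, 0.04, 0.00, -0.02])
        s = pd.DataFrame({"prop_ancestral": x, "delta_afr_nonafr": y})
        sx, sy = x - x.mean(), y - y.mean()
        r2_direct = (sx * sy).sum() ** 2 / ((sx**2).sum() * (sy**2).sum())
        assert rd.category_correlation(s) == pytest.approx(r2_direct)

    def test_too_few_categories_is_error(self):
        s = pd.DataFrame({"prop_ancestral": [0.1, 0.5], "delta_afr_nonafr": [0.0, 0.1]})
        with pytest.raises(ValueError):
            rd.category_correlation(s)


class TestCategorySummaries:
    def test_summaries_cover_all_categories(self, demo_panel, disease_table):
        s = rd.category_summaries(disease_table, demo_panel)
        assert set(s["category"]) == set(disease_table["category"].unique())
        assert (s["n_loci"] > 0).all()
        assert s["n_loci"].sum() == len(disease_table)
        assert ((s["prop_ancestral"] >= 0) & (s["prop_ancestral"] <= 1)).all()
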