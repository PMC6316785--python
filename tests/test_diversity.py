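"""Richness, Shannon diversity, paired tests, and incidence-derived summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lepisurvey as lp
from lepisurvey.survey import SiteSurveyTable


def _hand_shannon(counts):
    total = sum(c for c in counts if c > 0)
    return -sum(
        (c / total) * math.log(c / total) for c in counts if c > 0
    )


def _hand_paired_t(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in d) / (n - 1))
    return mean / (sd / math.sqrt(n)), n - 1


class TestShannonH:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 5, 5, 5], math.log(4)),
            ([10], 0.0),
            # hand evaluation of -(1/6 ln 1/6 + 2/6 ln 2/6 + 3/6 ln 3/6)
            ([1, 2, 3], 1.0114042647073516),
        ],
    )
    def test_known_values(self, counts, expected):
        assert lp.shannon_h(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_is_error(self):
        with pytest.raises(lp.ValidationError):
            lp.shannon_h([0, 0, 0])

    def test_negative_counts_rejected(self):
        with pytest.raises(lp.ValidationError):
            lp.shannon_h([3, -1])

    @given(
        counts=st.lists(st.integers(1, 50), min_size=1, max_size=8),
        factor=st.integers(2, 9),
    )
    def test_scale_invariance(self, counts, factor):
        assert lp.shannon_h([factor * c for c in counts]) == pytest.approx(
            lp.shannon_h(counts), abs=1e-12
        )

    def test_uniform_maximizes_h_over_fixed_support_compositions(self):
        # enumerate all 4-species compositions of 12 individuals with full support
        best = max(
            lp.shannon_h(c)
            for c in itertools.product(range(1, 10), repeat=4)
            if sum(c) == 12
        )
        assert best == pytest.approx(lp.shannon_h([3, 3, 3, 3]), abs=1e-12)

    @given(counts=st.lists(st.integers(0, 40), min_size=1, max_size=10))
    def test_agrees_with_direct_formula(self, counts):
        if sum(counts) == 0:
            return
        assert lp.shannon_h(counts) == pytest.approx(
            _hand_shannon(counts), abs=1e-10
        )


class TestPerSiteStats:
    def _table(self, rows, sites=None):
        return SiteSurveyTable(
            pd.DataFrame(rows, columns=SiteSurveyTable.COLUMNS), sites=sites
        )

    def test_richness_and_h_for_even_two_species_site(self):
        table = self._table(
            [("A", "pollard", "F", "a b", 2, ""), ("A", "pollard", "F", "c d", 2, "")]
        )
        (stat,) = lp.per_site_stats(table, "pollard")
        assert stat.richness == 2
        assert stat.shannon_h == pytest.approx(math.log(2), abs=1e-12)

    def test_empty_site_reports_zero_richness_missing_h(self):
        table = self._table(
            [("A", "pollard", "F", "a b", 1, "")],
            sites={"pollard": ["A", "B"]},
        )
        stats = {s.site_id: s for s in lp.per_site_stats(table, "pollard")}
        assert stats["B"].richness == 0 and stats["B"].shannon_h is None

    def test_unknown_method_is_configuration_error(self, paperlike):
        with pytest.raises(lp.ConfigurationError):
            lp.per_site_stats(paperlike.combined_table(), "sweepnet")

    def test_h_bounded_by_log_richness(self):
        world = lp.simulate_world(lp.default_model(2))
        for stat in lp.per_site_stats(world.combined_table(), "pollard"):
            if stat.richness >= 1 and stat.shannon_h is not None:
                assert 0 <= stat.shannon_h <= math.log(max(stat.richness, 2)) + 1e-12


class TestMeanRichnessIdentity:
    @pytest.mark.parametrize("seed", [0, 7, 23])
    @pytest.mark.parametrize("method", ["pollard", "malaise"])
    def test_site_mean_equals_incidence_sum_over_sites(self, seed, method):
        """Column sums and row sums of the detection matrix agree exactly."""
        world = lp.simulate_world(lp.default_model(seed))
        table = world.combined_table()
        stats = lp.per_site_stats(table, method)
        mean_direct = sum(s.richness for s in stats) / len(stats)
        summary = world.summarize()
        assert lp.mean_richness_from_incidence(summary, method) == pytest.approx(
            mean_direct, abs=1e-12
        )

    def test_inat_source_rejected(self, table1):
        with pytest.raises(lp.ConfigurationError):
            lp.mean_richness_from_incidence(table1, "inat")

    def test_empty_summary_gives_zero(self):
        empty = lp.summarize_incidence(None, [])
        assert lp.mean_richness_from_incidence(empty, "pollard", n_sites=16) == 0.0


class TestPairedTTest:
    def test_textbook_example(self):
        res = lp.paired_t_test([1, 2, 3, 4, 5, 6], [0] * 6)
        # t = 3.5 / (1.8708.../sqrt(6)) computed by hand
        assert res.statistic == pytest.approx(4.58257569, abs=1e-6)
        assert res.degrees_of_freedom == 5
        assert res.mean_difference == pytest.approx(3.5)

    def test_identical_samples_degenerate(self):
        with pytest.raises(lp.DegenerateInputError):
            lp.paired_t_test([1, 2, 3], [1, 2, 3])

    def test_constant_shift_degenerate(self):
        with pytest.raises(lp.DegenerateInputError):
            lp.paired_t_test([2, 3, 4], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(lp.ValidationError):
            lp.paired_t_test([1], [2])

    def test_sign_flip_antisymmetry(self):
        x, y = [3.0, 5.0, 4.0, 7.0], [1.0, 2.0, 6.0, 3.0]
        fwd = lp.paired_t_test(x, y)
        rev = lp.paired_t_test(y, x)
        assert fwd.statistic == pytest.approx(-rev.statistic, abs=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(5, 2, 10)
        y = x - rng.normal(1, 1.5, 10)
        res = lp.paired_t_test(x, y)
        t, df = _hand_paired_t(list(x), list(y))
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.degrees_of_freedom == df
        assert 0 <= res.p_value <= 1

    def test_paired_stat_test_matches_by_site(self, paperlike):
        table = paperlike.combined_table()
        a = lp.per_site_stats(table, "pollard")
        b = lp.per_site_stats(table, "malaise")
        res = lp.paired_stat_test(a, b, "richness")
        ax = {s.site_id: s.richness for s in a}
        bx = {s.site_id: s.richness for s in b}
        common = sorted(ax.keys() & bx.keys())
        direct = lp.paired_t_test([ax[k] for k in common], [bx[k] for k in common])
        assert res.statistic == pytest.approx(direct.statistic, abs=1e-12)


class TestIncidenceDerivedCounts:
    def test_source_richness(self, table1):
        assert lp.source_richness(table1, "pollard") == 27
        assert lp.source_richness(table1, "malaise") == 18
        assert lp.source_richness(table1, "inat") == 22

    def test_singletons(self, table1):
        assert lp.singleton_count(table1, "pollard") == 8

    def test_singletons_empty_and_saturated(self):
        empty = lp.summarize_incidence(None, [])
        assert lp.singleton_count(empty, "pollard") == 0
        everywhere = pd.DataFrame(
            {
                "pollard_sites": [16, 16],
                "malaise_sites": [16, 16],
                "inat_observations": [3, 3],
            },
            index=pd.MultiIndex.from_tuples(
                [("F", "a b"), ("F", "c d")], names=["family", "species"]
            ),
        )
        summary = lp.IncidenceSummary(everywhere, n_sites=16)
        assert lp.singleton_count(summary, "pollard") == 0

    def test_incidental_exclusives_are_the_two_known_species(self, table1):
        names = {t.species for t in lp.exclusive_species(table1, "inat")}
        assert names == {"Adelpha californica", "Limenitis lorquini"}

    def test_walk_exclusives_by_brute_force_enumeration(self, table1):
        expected = {
            (fam, sp)
            for (fam, sp), row in table1.table.iterrows()
            if row["pollard_sites"] > 0
            and row["malaise_sites"] == 0
            and row["inat_observations"] == 0
        }
        got = {(t.family, t.species) for t in lp.exclusive_species(table1, "pollard")}
        assert got == expected
        assert len(got) == 7

    def test_single_source_summary_is_all_exclusive(self):
        table = pd.DataFrame(
            {
                "pollard_sites": [2, 5],
                "malaise_sites": [0, 0],
                "inat_observations": [0, 0],
            },
            index=pd.MultiIndex.from_tuples(
                [("F", "a b"), ("F", "c d")], names=["family", "species"]
            ),
        )
        summary = lp.IncidenceSummary(table, n_sites=16)
        assert len(lp.exclusive_species(summary, "pollard")) == 2
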