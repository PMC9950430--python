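"""Seasonal statistics: Kruskal-Wallis, enrichment ratios, trends, pathways."""

from __future__ import annotations

import datetime as dt
import warnings

import numpy as np
import pytest
from scipy import stats

from magseason import seasonal_stats as ss
from magseason.coverage import CoverageTable
from magseason.model import SampleRecord
from magseason.normalize_filter import AbundanceMatrix


class TestKruskalWallis:
    def test_closed_form_untied_example(self):
        h, p = ss.kruskal_wallis_two_group([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(27 / 7)
        assert p == pytest.approx(float(stats.chi2.sf(27 / 7, 1)))

    def test_all_tied_degenerate(self):
        h, p = ss.kruskal_wallis_two_group([5, 5], [5, 5])
        assert h == 0.0 and p == 1.0

    def test_label_symmetry(self):
        a, b = [1.0, 3.5, 2.2, 9.0], [4.4, 0.1, 7.7]
        h1, p1 = ss.kruskal_wallis_two_group(a, b)
        h2, p2 = ss.kruskal_wallis_two_group(b, a)
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ss.kruskal_wallis_two_group([], [1, 2])

    def test_matches_scipy_with_ties(self):
        """Independent cross-check of the tie-corrected statistic."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.integers(0, 5, size=int(rng.integers(2, 10))).astype(float)
            b = rng.integers(0, 5, size=int(rng.integers(2, 10))).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            h, p = ss.kruskal_wallis_two_group(a, b)
            ref = stats.kruskal(a, b)
            assert h == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestCumulative:
    def test_sum_over_retained_orfs(self, tiny_model):
        abund = AbundanceMatrix(
            kind="orf", assay="metaT",
            values={("o1", "s1"): 0.2, ("o2", "s1"): 0.3, ("o4", "s1"): 9.0},
            sample_ids=["s1"],
        )
        cum = ss.mag_cumulative_transcripts(abund, tiny_model, {"o1", "o2"})
        assert cum[("magA", "s1")] == pytest.approx(0.5)

    def test_mag_without_retained_orfs_warns_and_is_zero(self, tiny_model):
        abund = AbundanceMatrix(
            kind="orf", assay="metaT", values={("o1", "s1"): 0.2}, sample_ids=["s1"]
        )
        with pytest.warns(UserWarning, match="magB"):
            cum = ss.mag_cumulative_transcripts(abund, tiny_model, {"o1"})
        assert cum[("magB", "s1")] == 0.0

    def test_permutation_invariant(self, tiny_model):
        abund = AbundanceMatrix(
            kind="orf", assay="metaT",
            values={("o1", "s1"): 0.2, ("o2", "s1"): 0.3, ("o3", "s1"): 0.4},
            sample_ids=["s1"],
        )
        a = ss.mag_cumulative_transcripts(abund, tiny_model, {"o1", "o2", "o3"})
        b = ss.mag_cumulative_transcripts(abund, tiny_model, {"o3", "o1", "o2"})
        assert a == b


class TestTestAllMags:
    def test_direction_and_bh_column(self, tiny_samples):
        cum = {}
        for i, s in enumerate(["sE1", "sE2"]):
            cum[("up", s)] = 1.0 + 0.01 * i
            cum[("same", s)] = 5.0
        for i, s in enumerate(["sL1", "sL2"]):
            cum[("up", s)] = 10.0 + 0.01 * i
            cum[("same", s)] = 5.0
        df = ss.test_all_mags(cum, tiny_samples, alpha=0.2).set_index("mag_id")
        assert df.loc["same", "direction"] == "none"
        assert df.loc["same", "H"] == 0.0
        assert set(df.columns) >= {"H", "p_value", "p_adj", "direction"}
        # 2+2 samples cannot beat alpha=0.2? H=3 -> p~0.083 -> increase
        assert df.loc["up", "direction"] == "increase"

    def test_missing_season_rejected(self, tiny_samples):
        early_only = [s for s in tiny_samples if s.season == "early"]
        with pytest.raises(ValueError):
            ss.test_all_mags({("m", "sE1"): 1.0, ("m", "sE2"): 2.0}, early_only)


def make_role_fixture(tiny_model, tiny_samples, values):
    abund = AbundanceMatrix(
        kind="orf", assay="metaT", values=values,
        sample_ids=[s.sample_id for s in tiny_samples],
    )
    return abund


class TestRoleEnrichment:
    def test_ratio_of_season_means(self, tiny_model, tiny_samples):
        # roleX carried by o1 (magA) and o3 (magA); early mean 0.2, late mean 4.0
        values = {
            ("o1", "sE1"): 0.1, ("o1", "sE2"): 0.3,
            ("o1", "sL1"): 4.0, ("o1", "sL2"): 4.0,
        }
        abund = make_role_fixture(tiny_model, tiny_samples, values)
        df = ss.role_enrichment(abund, tiny_model, tiny_samples, {"o1"}).set_index("role_id")
        assert df.loc["roleX", "ratio"] == pytest.approx(20.0)
        assert df.loc["roleX", "n_mags_detected"] == 1

    def test_zero_early_flag_policy(self, tiny_model, tiny_samples):
        values = {("o1", "sL1"): 1.0}
        abund = make_role_fixture(tiny_model, tiny_samples, values)
        df = ss.role_enrichment(abund, tiny_model, tiny_samples, {"o1"}).set_index("role_id")
        assert df.loc["roleX", "infinite"]
        assert np.isinf(df.loc["roleX", "ratio"])

    def test_zero_early_epsilon_policy_finite(self, tiny_model, tiny_samples):
        values = {("o1", "sL1"): 1.0}
        abund = make_role_fixture(tiny_model, tiny_samples, values)
        df = ss.role_enrichment(
            abund, tiny_model, tiny_samples, {"o1"}, pseudo_policy="epsilon"
        ).set_index("role_id")
        assert np.isfinite(df.loc["roleX", "ratio"])

    def test_late_scaling_equivariance(self, tiny_model, tiny_samples):
        """Multiplying all late-season abundances by k multiplies the ratio by k."""
        values = {
            ("o1", "sE1"): 0.5, ("o1", "sE2"): 0.7,
            ("o1", "sL1"): 2.0, ("o1", "sL2"): 3.0,
        }
        late = {s.sample_id for s in tiny_samples if s.season == "late"}
        scaled = {
            (o, s): v * 3.0 if s in late else v for (o, s), v in values.items()
        }
        r1 = ss.role_enrichment(
            make_role_fixture(tiny_model, tiny_samples, values),
            tiny_model, tiny_samples, {"o1"},
        ).set_index("role_id").loc["roleX", "ratio"]
        r2 = ss.role_enrichment(
            make_role_fixture(tiny_model, tiny_samples, scaled),
            tiny_model, tiny_samples, {"o1"},
        ).set_index("role_id").loc["roleX", "ratio"]
        assert r2 == pytest.approx(3.0 * r1)


class TestSubsystemTimeseries:
    def samples_over_dates(self, dates, reps=2):
        out = []
        for i, d in enumerate(dates):
            for r in range(reps):
                out.append(
                    SampleRecord(f"s{i}_{r}", "switchgrass", d, f"p{r}", "metaT")
                )
        return out

    def test_constant_series_flat_trend(self, tiny_model):
        dates = [dt.date(2017, 5, 15), dt.date(2017, 7, 1), dt.date(2017, 9, 1)]
        samples = self.samples_over_dates(dates)
        values = {("o1", s.sample_id): 2.0 for s in samples}
        abund = AbundanceMatrix(
            kind="orf", assay="metaT", values=values,
            sample_ids=[s.sample_id for s in samples],
        )
        ts, trend = ss.subsystem_timeseries(abund, tiny_model, samples, {"o1"})
        assert (ts["mean"] == 2.0).all()
        assert (ts["sem"] == 0.0).all()
        row = trend.iloc[0]
        assert abs(row.slope_per_day) < 1e-12
        assert row.p_value > 0.9

    def test_exactly_linear_recovered(self, tiny_model):
        dates = [dt.date(2017, 5, 15), dt.date(2017, 7, 1), dt.date(2017, 9, 1)]
        samples = self.samples_over_dates(dates)
        values = {
            ("o1", s.sample_id): 0.5 * s.day_of_year + 3.0 for s in samples
        }
        abund = AbundanceMatrix(
            kind="orf", assay="metaT", values=values,
            sample_ids=[s.sample_id for s in samples],
        )
        _, trend = ss.subsystem_timeseries(abund, tiny_model, samples, {"o1"})
        row = trend.iloc[0]
        assert row.slope_per_day == pytest.approx(0.5, abs=1e-9)
        assert row.intercept == pytest.approx(3.0, abs=1e-6)

    def test_fewer_than_three_dates_warns_and_omits_trend(self, tiny_model):
        dates = [dt.date(2017, 5, 15), dt.date(2017, 8, 1)]
        samples = self.samples_over_dates(dates)
        values = {("o1", s.sample_id): 1.0 for s in samples}
        abund = AbundanceMatrix(
            kind="orf", assay="metaT", values=values,
            sample_ids=[s.sample_id for s in samples],
        )
        with pytest.warns(UserWarning, match="fewer than 3"):
            ts, trend = ss.subsystem_timeseries(abund, tiny_model, samples, {"o1"})
        assert len(trend) == 0 and len(ts) > 0

    def test_rising_subsystem_detected(self, tiny_model):
        dates = [
            dt.date(2017, 5, 15), dt.date(2017, 6, 15),
            dt.date(2017, 7, 15), dt.date(2017, 8, 15),
        ]
        samples = self.samples_over_dates(dates, reps=3)
        rng = np.random.default_rng(2)
        values = {
            ("o1", s.sample_id): 0.1 * s.day_of_year + float(rng.normal(0, 0.5))
            for s in samples
        }
        abund = AbundanceMatrix(
            kind="orf", assay="metaT", values=values,
            sample_ids=[s.sample_id for s in samples],
        )
        _, trend = ss.subsystem_timeseries(abund, tiny_model, samples, {"o1"})
        row = trend.iloc[0]
        assert row.slope_per_day > 0 and row.p_value < 0.05


class TestPathwayActivity:
    def raw(self, values):
        return CoverageTable("orf", values)

    def test_detected_only_without_transcripts(self, tiny_model):
        defs = {"pw1": ["o1", "o2"]}
        df = ss.pathway_activity(tiny_model, defs, self.raw({})).set_index(
            ["mag_id", "pathway_id"]
        )
        assert df.loc[("magA", "pw1"), "status"] == "detected_only"
        assert df.loc[("magB", "pw1"), "status"] == "absent"

    def test_single_covered_member_activates(self, tiny_model):
        defs = {"pw1": ["o1", "o2"]}
        df = ss.pathway_activity(
            tiny_model, defs, self.raw({("o2", "s1"): 0.3})
        ).set_index(["mag_id", "pathway_id"])
        assert df.loc[("magA", "pw1"), "status"] == "active"

    def test_adding_reads_never_deactivates(self, tiny_model):
        defs = {"pw1": ["o1"]}
        base = {("o1", "s1"): 0.3}
        more = {("o1", "s1"): 0.3, ("o1", "s2"): 1.0}
        s1 = ss.pathway_activity(tiny_model, defs, self.raw(base))
        s2 = ss.pathway_activity(tiny_model, defs, self.raw(more))
        rank = {"absent": 0, "detected_only": 1, "active": 2}
        for (_, r1), (_, r2) in zip(s1.iterrows(), s2.iterrows()):
            assert rank[r2.status] >= rank[r1.status]

    def test_unknown_orf_named(self, tiny_model):
        with pytest.raises(KeyError, match="ghost"):
            ss.pathway_activity(tiny_model, {"pw": ["ghost"]}, self.raw({}))


class TestRolePrevalence:
    def test_counts_mags_with_retained_orfs(self, tiny_model):
        # roleX on o1 (magA) and o3 (magA): prevalence 1; o4 roleZ on magB
        prev = ss.role_prevalence(tiny_model, {"o1", "o3", "o4"})
        assert prev == {"roleX": 1, "roleZ": 1}

    def test_filtered_out_role_absent(self, tiny_model):
        prev = ss.role_prevalence(tiny_model, {"o2"})
        assert "roleX" not in prev

    def test_bounded_by_mag_count(self, tiny_model):
        prev = ss.role_prevalence(tiny_model, set(tiny_model.orfs))
        assert all(v <= len(tiny_model.mags) for v in prev.values())
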