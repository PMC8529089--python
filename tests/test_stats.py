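import math

import numpy as np
import pytest

from fechsurvey.io_metadata import Dataset, GenomeMeta, ProteinRecord
from fechsurvey.stats import (
    CysteineProfile,
    binned_likelihood,
    cooccurrence,
    crosstab,
    cysteine_profile,
    environment_group_shares,
    gc_summary,
    length_cys_correlation,
    logistic_fit,
    round_percent,
    species_mcf_status,
    temperature_table,
)


def _profiles(counts, length=300):
    return [
        CysteineProfile(f"r{i}", c, c / length, length)
        for i, c in enumerate(counts)
    ]


class TestCysteineProfile:
    def test_all_cysteine(self):
        p = cysteine_profile(ProteinRecord("r", "g", "CCCC"))
        assert p.cys_count == 4 and p.cys_fraction == 1.0

    def test_no_cysteine(self):
        p = cysteine_profile(ProteinRecord("r", "g", "MHAG"))
        assert p.cys_count == 0 and p.cys_fraction == 0.0

    def test_counts_planted_cysteines(self):
        rng = np.random.default_rng(3)
        seq = list("A" * 300)
        pos = rng.choice(300, size=14, replace=False)
        for i in pos:
            seq[i] = "C"
        p = cysteine_profile(ProteinRecord("r", "g", "".join(seq)))
        assert p.cys_count == 14

    def test_respects_trim_span(self):
        p = cysteine_profile(ProteinRecord("r", "g", "CCAACC", trim_span=(3, 6)))
        assert p.cys_count == 2 and p.length == 4


class TestBinnedLikelihood:
    def test_small_bin_binomial_se(self):
        """k=2 of n=3: p=0.67 with the large +/-0.27 binomial SE."""
        profiles = _profiles([11, 12, 13])
        labels = {"r0": True, "r1": True, "r2": False}
        (bl,) = binned_likelihood(profiles, labels, bins=[(11, None)])
        assert bl.n == 3 and bl.k == 2
        assert round(bl.p_hat, 2) == 0.67
        assert round(bl.se, 2) == 0.27

    def test_zero_successes(self):
        profiles = _profiles([1] * 10)
        labels = {p.record_id: False for p in profiles}
        (bl,) = binned_likelihood(profiles, labels, bins=[(0, 3)])
        assert bl.p_hat == 0.0 and bl.se == 0.0

    def test_half_successes_se(self):
        profiles = _profiles([5] * 100)
        labels = {p.record_id: i < 50 for i, p in enumerate(profiles)}
        (bl,) = binned_likelihood(profiles, labels, bins=[(4, 6)])
        assert bl.se == pytest.approx(0.05)

    def test_empty_bin_flagged_undefined(self):
        profiles = _profiles([2, 3])
        labels = {"r0": False, "r1": False}
        bins = binned_likelihood(profiles, labels, bins=[(0, 3), (11, None)])
        assert bins[1].n == 0
        assert math.isnan(bins[1].p_hat) and math.isnan(bins[1].se)

    def test_bin_totals_cover_cohort(self):
        counts = list(range(15)) * 3
        profiles = _profiles(counts)
        labels = {p.record_id: False for p in profiles}
        bins = binned_likelihood(
            profiles, labels, bins=[(0, 3), (4, 5), (6, 10), (11, None)]
        )
        assert sum(b.n for b in bins) == len(profiles)

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            binned_likelihood([], {}, bins=[(0, 6), (6, 10)])


def grid_search_mle(x, y, rounds=26, span=16.0, points=21):
    """Independent likelihood maximizer: nested grid refinement.

    The search box halves each round (gentle shrink: the log-likelihood
    ridge is diagonal in (b0, b1), so the per-round winner can sit well
    away from the optimum along the ridge).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def ll(b0, b1):
        eta = np.clip(b0 + b1 * x, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        return np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

    c0, c1, h = 0.0, 0.0, span / 2
    for _ in range(rounds):
        grid0 = np.linspace(c0 - h, c0 + h, points)
        grid1 = np.linspace(c1 - h, c1 + h, points)
        best = (-np.inf, c0, c1)
        for b0 in grid0:
            for b1 in grid1:
                v = ll(b0, b1)
                if v > best[0]:
                    best = (v, b0, b1)
        _, c0, c1 = best
        h = h / 2
    return c0, c1


class TestLogisticFit:
    def test_symmetric_data_gives_zero_slope(self):
        fit = logistic_fit([0, 0, 1, 1], [0, 1, 0, 1])
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)
        assert fit.odds_ratio == pytest.approx(1.0)

    def test_mle_matches_grid_search_oracle(self):
        """IRLS optimum equals an independent grid-refined maximizer."""
        rng = np.random.default_rng(19)
        x = rng.integers(0, 13, size=40).astype(float)
        p = 1 / (1 + np.exp(-(-3.0 + 0.8 * x)))
        y = (rng.random(40) < p).astype(int)
        assert 0 < y.sum() < 40
        fit = logistic_fit(x, y)
        g0, g1 = grid_search_mle(x, y)
        assert fit.beta0 == pytest.approx(g0, abs=1e-4)
        assert fit.beta1 == pytest.approx(g1, abs=1e-4)

    def test_score_equations_satisfied_at_optimum(self):
        rng = np.random.default_rng(23)
        x = rng.poisson(4.4, size=300).astype(float)
        p = 1 / (1 + np.exp(-(-5.0 + 0.9 * x)))
        y = (rng.random(300) < p).astype(int)
        fit = logistic_fit(x, y)
        assert fit.converged
        mu = 1 / (1 + np.exp(-(fit.beta0 + fit.beta1 * x)))
        score = np.array([np.sum(y - mu), np.sum((y - mu) * x)])
        assert np.max(np.abs(score)) < 1e-6

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        x = rng.integers(0, 14, size=200).astype(float)
        p = 1 / (1 + np.exp(-(-4.0 + 0.9 * x)))
        y = (rng.random(200) < p).astype(int)
        fit = logistic_fit(x, y)
        sm_fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.beta0 == pytest.approx(sm_fit.params[0], abs=1e-6)
        assert fit.beta1 == pytest.approx(sm_fit.params[1], abs=1e-6)
        assert fit.se1 == pytest.approx(sm_fit.bse[1], rel=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            logistic_fit([1, 2, 3], [1, 1, 1])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_fit([2, 2, 2, 2], [0, 1, 0, 1])

    def test_complete_separation_flagged_not_raised(self):
        fit = logistic_fit([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert not fit.converged
        assert fit.odds_ratio > 1

    def test_ci_brackets_odds_ratio(self):
        rng = np.random.default_rng(37)
        x = rng.poisson(4, 500).astype(float)
        y = (rng.random(500) < 1 / (1 + np.exp(-(-4 + 0.9 * x)))).astype(int)
        fit = logistic_fit(x, y)
        assert fit.ci95[0] <= fit.odds_ratio <= fit.ci95[1]


def _dataset(rows):
    """rows: list of (genome kwargs, mcf flag); one record per genome."""
    ds = Dataset()
    mcf = {}
    for i, (kwargs, is_mcf) in enumerate(rows):
        gid = f"g{i:03d}"
        rid = f"r{i:03d}"
        ds.genomes[gid] = GenomeMeta(genome_id=gid, **kwargs)
        ds.records.append(ProteinRecord(rid, gid, "MH"))
        mcf[rid] = is_mcf
    return ds, mcf


class TestCrosstab:
    def test_per_row_percent(self):
        rows = [({"phylum": "A"}, True)] * 3 + [({"phylum": "A"}, False)] * 1
        ds, mcf = _dataset(rows)
        ct = crosstab(ds, mcf, "phylum", "per_row_total")
        assert ct.loc[0, "total"] == 4
        assert ct.loc[0, "mcf"] == 3
        assert ct.loc[0, "percent"] == 75

    def test_mcf_total_percent(self):
        rows = (
            [({"environment": "aquatic_marine"}, True)] * 3
            + [({"environment": "terrestrial_soil"}, True)] * 1
            + [({"environment": "terrestrial_soil"}, False)] * 5
        )
        ds, mcf = _dataset(rows)
        ct = crosstab(ds, mcf, "environment", "mcf_total")
        aquatic = ct[ct.category == "aquatic_marine"].iloc[0]
        assert aquatic.percent == 75  # 3 of 4 MCF species

    def test_rounding_half_up(self):
        assert round_percent(0.955) == 96
        assert round_percent(0.111) == 11
        assert round_percent(0.25) == 25
        assert round_percent(0.005) == 1

    def test_empty_dataset_gives_empty_table(self):
        ds = Dataset()
        ct = crosstab(ds, {}, "phylum")
        assert ct.empty

    def test_species_collapse_any_record_mcf(self):
        ds = Dataset()
        ds.genomes["g1"] = GenomeMeta(genome_id="g1", phylum="A")
        ds.records = [
            ProteinRecord("r1", "g1", "MH"),
            ProteinRecord("r2", "g1", "MH"),
        ]
        status = species_mcf_status(ds, {"r1": False, "r2": True})
        assert status == {"g1": True}

    def test_totals_sum_to_cohort(self):
        rows = [({"phylum": p}, i % 3 == 0) for i, p in enumerate("ABCA" * 10)]
        ds, mcf = _dataset(rows)
        ct = crosstab(ds, mcf, "phylum")
        assert ct.total.sum() == len(ds.genomes)


class TestEnvironmentGroups:
    def test_group_shares_sum_structure(self):
        rows = (
            [({"environment": "aquatic_marine"}, True)] * 2
            + [({"environment": "aquatic_freshwater"}, True)] * 2
            + [({"environment": "terrestrial_soil"}, True)] * 1
            + [({"environment": "host_human"}, False)] * 5
        )
        ds, mcf = _dataset(rows)
        ct = crosstab(ds, mcf, "environment", "mcf_total")
        shares = environment_group_shares(ct)
        assert shares["aquatic"] == 80
        assert shares["terrestrial"] == 20
        assert shares["host"] == 0


class TestCooccurrence:
    def test_cells_mutually_exclusive(self):
        rows = [
            ({"oxygen_req": "aerobic", "has_cog0633": True}, False),
            ({"oxygen_req": "aerobic", "has_cog0633": True}, True),
            ({"oxygen_req": "aerobic", "has_cog0633": False}, True),
            ({"oxygen_req": "aerobic", "has_cog0633": False}, False),
        ]
        ds, mcf = _dataset(rows)
        table = cooccurrence(ds, mcf)
        row = table[table.oxygen_req == "aerobic"].iloc[0]
        assert (row.neither, row.cog_only, row.mcf_only, row.both) == (1, 1, 1, 1)

    def test_row_sums_equal_class_census(self):
        rng = np.random.default_rng(41)
        rows = [
            (
                {
                    "oxygen_req": ["aerobic", "anaerobic", "facultative"][i % 3],
                    "has_cog0633": bool(rng.random() < 0.5),
                },
                bool(rng.random() < 0.3),
            )
            for i in range(90)
        ]
        ds, mcf = _dataset(rows)
        table = cooccurrence(ds, mcf)
        for _, row in table.iterrows():
            census = sum(
                1 for g in ds.genomes.values() if g.oxygen_req == row.oxygen_req
            )
            assert row.neither + row.cog_only + row.mcf_only + row.both == census


class TestGcSummary:
    def test_two_group_mean(self):
        rows = [({"gc_percent": 40.0}, True), ({"gc_percent": 60.0}, True)]
        ds, mcf = _dataset(rows)
        means = gc_summary(ds, mcf)
        assert means["all"] == pytest.approx(50.0)
        assert means["mcf"] == pytest.approx(50.0)
        assert math.isnan(means["non_mcf"])

    def test_singleton_group(self):
        rows = [({"gc_percent": 47.5}, False)]
        ds, mcf = _dataset(rows)
        assert gc_summary(ds, mcf)["non_mcf"] == pytest.approx(47.5)

    def test_planted_means_recovered(self):
        rng = np.random.default_rng(43)
        rows = []
        for _ in range(200):
            mcf = bool(rng.random() < 0.3)
            gc = rng.normal(45 if mcf else 55, 0.5)
            rows.append(({"gc_percent": float(np.clip(gc, 0, 100))}, mcf))
        ds, mcf_map = _dataset(rows)
        means = gc_summary(ds, mcf_map)
        assert means["mcf"] == pytest.approx(45, abs=0.5)
        assert means["non_mcf"] == pytest.approx(55, abs=0.5)


class TestTemperatureTable:
    def test_counts_by_class(self):
        rows = [
            ({"temp_range": "mesophile"}, True),
            ({"temp_range": "mesophile"}, False),
            ({"temp_range": "thermophile"}, False),
        ]
        ds, mcf = _dataset(rows)
        table = temperature_table(ds, mcf)
        meso = table[table.temp_range == "mesophile"].iloc[0]
        assert meso.total == 2 and meso.mcf == 1
        assert table.total.sum() == 3


class TestLengthCysCorrelation:
    def test_perfect_linear(self):
        profiles = [
            CysteineProfile(f"r{i}", i, i / (100 + 10 * i), 100 + 10 * i)
            for i in range(10)
        ]
        r, defined = length_cys_correlation(profiles)
        assert defined and r == pytest.approx(1.0)

    def test_constant_counts_undefined(self):
        profiles = [
            CysteineProfile(f"r{i}", 4, 0.01, 100 + i) for i in range(10)
        ]
        r, defined = length_cys_correlation(profiles)
        assert not defined and math.isnan(r)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(47)
        profiles = [
            CysteineProfile(
                f"r{i}", int(rng.integers(0, 15)), 0.01, int(rng.integers(270, 684))
            )
            for i in range(400)
        ]
        r, defined = length_cys_correlation(profiles)
        assert defined and abs(r) < 0.15
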