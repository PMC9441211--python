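"""Rate tables, rounding, regression, association, and distributions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathreq_audit import analytics
from pathreq_audit.analytics import (
    cases_to_frame,
    distribution_summary,
    fit_univariate_logistic,
    present_rate_table,
    rate_table,
    rate_table_from_counts,
    round_half_away,
    volume_association,
)
from pathreq_audit.types import SpsProfile


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (0.6105733, 0.611),   # half-up where banker's would also round up
        (0.0005, 0.001),      # exact half rounds away from zero
        (0.0025, 0.003),      # banker's would give 0.002
        (-0.0005, -0.001),
        (0.9937106, 0.994),
        (0.2009264, 0.201),
    ])
    def test_half_away(self, x, expected):
        assert round_half_away(x, 3) == expected


class TestRateTable:
    def test_all_chp_rate_one(self, small_cohort):
        _, _, _, _, classified = small_cohort
        df = cases_to_frame(classified)
        df["status"] = "CHP"
        df["is_chp"] = True
        table = present_rate_table(rate_table(df, ["site"]))
        assert (table["rate"] == 1.0).all()

    def test_printed_pair_rate(self):
        table = present_rate_table(rate_table_from_counts(
            ["Gastrointestinal"], [185_863], [113_483],
            stratifier="tissue_group"))
        assert table.loc[0, "rate"] == 0.611

    def test_matches_bruteforce_recount(self, small_cohort):
        _, _, _, _, classified = small_cohort
        df = cases_to_frame(classified)
        table = rate_table(df, ["site", "year"])
        assert int(table["volume"].sum()) == len(df)
        assert int(table["chp"].sum()) == int(df["is_chp"].sum())
        for _, row in table.iterrows():
            sub = df[(df["site"] == row["site"]) & (df["year"] == row["year"])]
            assert len(sub) == row["volume"]
            assert int(sub["is_chp"].sum()) == row["chp"]
            assert row["rate"] == pytest.approx(sub["is_chp"].mean())

    def test_fractions_sum_to_one(self, small_cohort):
        _, _, _, _, classified = small_cohort
        table = rate_table(cases_to_frame(classified), ["tissue_group"])
        assert table["fraction_of_total"].sum() == pytest.approx(1.0)

    def test_unknown_stratifier_error(self, small_cohort):
        _, _, _, _, classified = small_cohort
        with pytest.raises(KeyError):
            rate_table(cases_to_frame(classified), ["no_such_column"])


def _binary_cohort(rng, n, beta, p_x=0.5, intercept=0.0):
    x = (rng.random(n) < p_x).astype(float)
    p = 1 / (1 + np.exp(-(intercept + beta * x)))
    y = rng.random(n) < p
    return pd.DataFrame({
        "status": np.where(y, "CHP", "NIA"), "x": x,
    })


class TestRegression:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(8)
        df = _binary_cohort(rng, 20_000, beta=1.0)
        res = fit_univariate_logistic(df, "x", categorical=False)
        assert res.params["x"] == pytest.approx(1.0, abs=0.15)
        assert res.p_value < 1e-4
        assert res.converged and not res.separation

    def test_categorical_dummy_coding_against_modal_level(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "status": np.where(rng.random(3000) < 0.7, "CHP", "NAOR"),
            "g": rng.choice(["a", "b", "c"], size=3000, p=[0.6, 0.3, 0.1]),
        })
        res = fit_univariate_logistic(df, "g")
        assert res.coding == "categorical"
        assert res.reference_level == "a"
        assert set(res.params) == {"const", "g_b", "g_c"}

    def test_degenerate_predictor_error(self):
        df = pd.DataFrame({"status": ["CHP", "NIA"] * 10, "x": [1.0] * 20})
        with pytest.raises(ValueError, match="degenerate"):
            fit_univariate_logistic(df, "x", categorical=False)

    def test_perfect_separation_flagged(self):
        df = pd.DataFrame({
            "status": ["CHP"] * 50 + ["NIA"] * 50,
            "x": [1.0] * 50 + [0.0] * 50,
        })
        with pytest.warns():
            res = fit_univariate_logistic(df, "x", categorical=False)
        assert res.separation
        assert res.params  # coefficients still reported

    def test_lrt_matches_direct_llf_difference(self):
        rng = np.random.default_rng(10)
        df = _binary_cohort(rng, 5000, beta=0.5)
        res = fit_univariate_logistic(df, "x", categorical=False)
        stat = 2 * (res.llf - res.llf_null)
        assert res.p_value == pytest.approx(
            float(stats.chi2.sf(stat, 1)), rel=1e-9)


class TestVolumeAssociation:
    def _profiles(self, volumes, rates):
        return [SpsProfile(sps_code=f"S{i}", assigned_site="x",
                           n_cases=v, n_chp=int(round(v * r)))
                for i, (v, r) in enumerate(zip(volumes, rates))]

    def test_perfect_antirank(self):
        volumes = [100, 200, 300, 400, 500]
        rates = [0.9, 0.8, 0.7, 0.6, 0.5]
        rho, _ = volume_association(self._profiles(volumes, rates))
        assert rho == pytest.approx(-1.0)

    def test_null_simulation_near_zero(self):
        # independent volume and rate: rho ~ 0, averaged over replicates to
        # keep the check well inside the null sampling noise (SD ~ 1/sqrt(n))
        rng = np.random.default_rng(12)
        rhos = []
        for _ in range(5):
            volumes = rng.integers(200, 5000, size=300)
            rates = rng.uniform(0.3, 1.0, size=300)
            rho, _ = volume_association(self._profiles(volumes, rates))
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1
        assert max(abs(r) for r in rhos) < 4 / np.sqrt(299)

    def test_tied_ranks_match_rank_formula(self):
        volumes = [200, 200, 300, 300, 300, 400]
        rates = [0.5, 0.6, 0.7, 0.8, 0.55, 0.9]
        rho, _ = volume_association(self._profiles(volumes, rates))
        # brute force: Pearson correlation of midranks
        def midranks(v):
            v = np.asarray(v, dtype=float)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks
        rv, rr = midranks(volumes), midranks(
            [p.chp_rate for p in self._profiles(volumes, rates)])
        expected = np.corrcoef(rv, rr)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            volume_association(self._profiles([100, 200], [0.5, 0.6]))


class TestDistribution:
    def _profiles(self, rates):
        return [SpsProfile(sps_code=f"S{i}", assigned_site="x",
                           n_cases=1000, n_chp=int(round(1000 * r)))
                for i, r in enumerate(rates)]

    def test_all_rates_one_single_terminal_bin(self):
        d = distribution_summary(self._profiles([1.0] * 25))
        assert d.counts[-1] == 25
        assert d.counts[:-1].sum() == 0

    def test_counts_conserved(self, small_cohort):
        _, _, _, _, classified = small_cohort
        from pathreq_audit.attribution import sps_profiles
        profiles = sps_profiles(classified, min_cases=5)
        d = distribution_summary(profiles)
        assert int(d.counts.sum()) == len(profiles)
        assert len(d.bin_edges) == 21

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(13)
        d = distribution_summary(self._profiles(rng.uniform(0.2, 1.0, 100)))
        assert d.density_integral() == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_rates_still_normalised(self):
        d = distribution_summary(self._profiles([0.8] * 5))
        assert d.density_integral() == pytest.approx(1.0, abs=1e-3)
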