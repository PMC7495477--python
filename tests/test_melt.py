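import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from memstab.melt import (
    TEN_TEMP_GRID,
    MeltCurve,
    MeltFitError,
    MeltSummary,
    analyse_campaign,
    classify_by_delta_tm,
    delta_tm_with_error,
    fit_melting_curve,
    four_pl,
    load_melt_curves,
    propagate_sem,
    single_temperature_screen,
    summarise_tm,
)
from memstab.simulate import FixtureSpec, generate_melt_curves


def _clean_curve(tm=49.3, slope=0.5, construct="WT", rep="r1",
                 grid=TEN_TEMP_GRID):
    temps = np.asarray(grid, dtype=float)
    return MeltCurve(construct, rep, temps, four_pl(temps, tm, slope, 1.0, 0.0),
                     1.0)


class TestCurveFitting:
    def test_noise_free_recovery_is_exact(self):
        fit = fit_melting_curve(_clean_curve(tm=49.3))
        assert fit.tm == pytest.approx(49.3, abs=1e-6)
        assert fit.reliable

    def test_noisy_recovery_within_half_degree(self):
        errors = []
        for seed in range(30):
            curves = generate_melt_curves(FixtureSpec(seed=seed,
                                                      melt_noise_sd=0.03),
                                          true_tm=49.3, n_repeats=1)
            errors.append(abs(fit_melting_curve(curves[0]).tm - 49.3))
        assert np.median(errors) < 0.5

    def test_monotone_signal_flagged_unreliable(self):
        temps = np.asarray(TEN_TEMP_GRID)
        curve = MeltCurve("X", "r1", temps, np.linspace(0.2, 1.0, len(temps)),
                          1.0)
        assert not fit_melting_curve(curve).reliable

    def test_transition_outside_grid_flagged(self):
        # melt far above the sampled range: no inflection within the grid
        fit = fit_melting_curve(_clean_curve(tm=150.0))
        assert not fit.reliable

    def test_too_few_temperatures_rejected(self):
        with pytest.raises(ValueError, match="5 distinct"):
            MeltCurve("X", "r1", [20, 30, 40, 50], [1, 1, 0.5, 0], 1.0)


class TestSummaries:
    def test_mean_and_sem(self):
        fits = [fit_melting_curve(_clean_curve(tm=t, rep=f"r{t}"))
                for t in (50.0, 52.0, 54.0)]
        s = summarise_tm(fits, "X")
        assert s.mean_tm == pytest.approx(52.0, abs=1e-5)
        assert s.sem_tm == pytest.approx(2.0 / math.sqrt(3), abs=1e-5)

    def test_single_repeat_has_no_sem(self):
        s = summarise_tm([fit_melting_curve(_clean_curve(tm=57.4))], "VAR1")
        assert s.mean_tm == pytest.approx(57.4, abs=1e-5)
        assert s.sem_tm is None

    def test_identical_repeats_zero_sem(self):
        fits = [fit_melting_curve(_clean_curve(tm=50.0, rep=f"r{i}"))
                for i in range(3)]
        assert summarise_tm(fits, "X").sem_tm == pytest.approx(0.0, abs=1e-6)


class TestErrorPropagation:
    @pytest.mark.parametrize("sem_wt,sem_var,expected", [
        (0.9, 1.2, 1.5),
        (0.7, 1.1, 1.3),
        (0.7, 0.4, 0.8),
    ])
    def test_printed_quadrature_pairs(self, sem_wt, sem_var, expected):
        assert round(propagate_sem(sem_wt, sem_var), 1) == expected

    def test_zero_variant_sem_identity(self):
        assert propagate_sem(0.9, 0.0) == pytest.approx(0.9)

    @given(st.floats(0, 10, allow_nan=False), st.floats(0, 10, allow_nan=False))
    def test_quadrature_dominates_inputs(self, a, b):
        out = propagate_sem(a, b)
        assert out >= max(a, b) - 1e-12
        if a == b:
            assert out == pytest.approx(math.sqrt(2) * a)

    def test_missing_sem_propagates_to_missing(self):
        var = MeltSummary("v", 50.0, None, 1)
        wt = MeltSummary("WT", 49.3, 0.9, 8)
        out = delta_tm_with_error(var, wt)
        assert out.delta_tm == pytest.approx(0.7)
        assert out.sem_delta_tm is None


class TestClassification:
    def _summary(self, name, delta, sem):
        s = MeltSummary(name, 50.0, None, 3)
        s.delta_tm = delta
        s.sem_delta_tm = sem
        return s

    def test_campaign_cutoff_is_mean_sem(self):
        summaries = [self._summary("a", 13.0, 1.4),
                     self._summary("b", 0.0, 1.2),
                     self._summary("c", -5.3, 1.3)]
        cutoff = classify_by_delta_tm(summaries)
        assert cutoff == pytest.approx(1.3)
        assert [s.status for s in summaries] == [
            "stabilising", "neutral", "destabilising"]

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        deltas = rng.normal(0, 3, 20)
        pos = [self._summary(f"p{i}", d, 1.0) for i, d in enumerate(deltas)]
        neg = [self._summary(f"n{i}", -d, 1.0) for i, d in enumerate(deltas)]
        classify_by_delta_tm(pos)
        classify_by_delta_tm(neg)
        count = lambda ss, lab: sum(s.status == lab for s in ss)
        assert count(pos, "stabilising") == count(neg, "destabilising")
        assert count(pos, "neutral") == count(neg, "neutral")

    def test_no_sems_demands_explicit_cutoff(self):
        with pytest.raises(MeltFitError, match="cutoff"):
            classify_by_delta_tm([self._summary("a", 1.0, None)])
        cutoff = classify_by_delta_tm([self._summary("a", 1.0, None)],
                                      cutoff=0.5)
        assert cutoff == 0.5


class TestSingleTemperatureScreen:
    def test_engineered_cutoff_and_hit(self):
        # pooled measurements built so the 95% CI lower bound is ~0.55
        from scipy.stats import t as t_dist
        n, sd, target_low = 40, 0.25, 0.55
        mean = target_low + t_dist.ppf(0.975, n - 1) * sd / math.sqrt(n)
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, n)
        vals = (vals - vals.mean()) / vals.std(ddof=1) * sd + mean
        rows = [{"construct": f"v{i}", "survival": v}
                for i, v in enumerate(vals)]
        rows += [{"construct": "hit", "survival": 0.60}] * 3
        rows += [{"construct": "miss", "survival": 0.50}] * 3
        # keep the pooled stats of the engineered block dominant
        df = pd.DataFrame(rows[:n])
        out = single_temperature_screen(df)
        assert out.attrs["cutoff"] == pytest.approx(target_low, abs=1e-9)
        full = single_temperature_screen(pd.DataFrame(rows),
                                         cutoff=out.attrs["cutoff"])
        by = full.set_index("construct")
        assert bool(by.loc["hit", "hit"])
        assert not bool(by.loc["miss", "hit"])

    def test_boundary_is_strict(self):
        df = pd.DataFrame({"construct": ["a"] * 5,
                           "survival": [0.5] * 5})
        out = single_temperature_screen(df, cutoff=0.5)
        assert not out["hit"].any()

    def test_wildtype_is_a_hit_in_self_consistent_data(self):
        rng = np.random.default_rng(1)
        rows = [{"construct": "WT", "survival": v}
                for v in rng.normal(1.0, 0.05, 8)]
        rows += [{"construct": f"v{i}", "survival": v}
                 for i, v in enumerate(rng.uniform(0.2, 0.9, 30))]
        out = single_temperature_screen(pd.DataFrame(rows))
        assert bool(out.set_index("construct").loc["WT", "hit"])

    def test_too_few_measurements_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            single_temperature_screen(pd.DataFrame(
                {"construct": ["a", "b"], "survival": [0.5, 0.6]}))


class TestCampaignIO:
    def test_double_band_intensities_summed(self, tmp_path):
        temps = list(TEN_TEMP_GRID)
        rows = []
        for T in ["ice"] + temps:
            y = 1.0 if T == "ice" else float(
                four_pl(np.array([float(T)]), 49.3, 0.5, 1.0, 0.0)[0])
            rows.append({"construct": "WT", "repeat": "r1", "temperature": T,
                         "intensity": 600 * y, "intensity_band2": 400 * y})
        path = tmp_path / "curves.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        curves = load_melt_curves(path)
        assert curves[0].ice_signal == pytest.approx(1000.0)
        fit = fit_melting_curve(curves[0])
        assert fit.tm == pytest.approx(49.3, abs=1e-4)

    def test_campaign_table_matches_hand_built_summaries(self, tmp_path):
        rows = []
        for construct, tm in [("WT", 49.3), ("VAR", 62.3)]:
            for rep, jitter in [("r1", -1.0), ("r2", 0.0), ("r3", 1.0)]:
                temps = np.asarray(TEN_TEMP_GRID)
                y = four_pl(temps, tm + jitter, 0.5, 1.0, 0.0)
                rows.append({"construct": construct, "repeat": rep,
                             "temperature": "ice", "intensity": 1.0})
                rows += [{"construct": construct, "repeat": rep,
                          "temperature": T, "intensity": v}
                         for T, v in zip(temps, y)]
        path = tmp_path / "c.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        out = analyse_campaign(load_melt_curves(path), "WT")
        var = out.set_index("construct").loc["VAR"]
        assert var["delta_tm"] == pytest.approx(13.0, abs=0.05)
        assert var["status"] == "stabilising"
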