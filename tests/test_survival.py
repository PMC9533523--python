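import numpy as np
import pandas as pd
import pytest

from deepimmune.survival import (
    c_index,
    cox_fit,
    cumulative_dynamic_auc,
    iauc,
    km_curve,
    logrank,
    stratified_km,
    survival_at,
    univariate_selection,
)
from deepimmune.synthetic_data import simulate_exponential_group


def brute_force_c_index(risk, times, events):
    """Independent pair-enumeration oracle for Harrell's C."""
    conc = 0.0
    pairs = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = events[i] == 1 and (
                times[i] < times[j]
                or (times[i] == times[j] and events[j] == 0)
            )
            if not comparable:
                continue
            pairs += 1
            if risk[i] > risk[j]:
                conc += 1.0
            elif risk[i] == risk[j]:
                conc += 0.5
    return conc / pairs


def two_group_logrank_oracle(times, events, groups):
    """Hand-style observed-minus-expected oracle over explicit risk sets."""
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(df.loc[df.e == 1, "t"].unique()):
        risk = df[df.t >= t]
        n = len(risk)
        n1 = len(risk[risk.g == 1])
        d = len(df[(df.t == t) & (df.e == 1)])
        d1 = len(df[(df.t == t) & (df.e == 1) & (df.g == 1)])
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKaplanMeier:
    def test_product_limit_oracle(self):
        # events at 1,2,3,4 and a censored 6: S(5) = (4/5)(3/4)(2/3)(1/2) = 0.2
        curve = km_curve([1, 2, 3, 4, 6], [1, 1, 1, 1, 0])
        assert survival_at(curve, 5.0) == pytest.approx(0.2)

    def test_no_events(self):
        curve = km_curve([1, 2, 3], [0, 0, 0])
        for t in (0.0, 1.5, 10.0):
            assert survival_at(curve, t) == 1.0

    def test_no_censoring_equals_empirical(self, rng):
        times = rng.exponential(3.0, 50)
        curve = km_curve(times, np.ones(50, dtype=int))
        for t in np.linspace(0.1, 10, 25):
            assert survival_at(curve, t) == pytest.approx(np.mean(times > t))

    def test_right_continuity_at_event_time(self):
        curve = km_curve([1, 2, 3, 4, 6], [1, 1, 1, 1, 0])
        assert survival_at(curve, 1.0) == pytest.approx(0.8)
        assert survival_at(curve, 1.0, left=True) == pytest.approx(1.0)

    def test_negative_time_rejected(self):
        curve = km_curve([1.0], [1])
        with pytest.raises(ValueError):
            survival_at(curve, -0.1)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(4.0, 200)
        events = (rng.random(200) < 0.7).astype(int)
        curve = km_curve(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in np.linspace(0.2, 12, 30):
            assert survival_at(curve, t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])


class TestLogrank:
    def test_duplicated_groups_null(self):
        t = [1, 2, 3, 4, 6.0] * 2
        e = [1, 1, 1, 1, 0] * 2
        g = [0] * 5 + [1] * 5
        chi2, p = logrank(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_small_table_matches_oracle(self, rng):
        for _ in range(10):
            n = 8
            times = np.round(rng.exponential(3.0, n), 1) + 0.1
            events = (rng.random(n) < 0.8).astype(int)
            groups = rng.integers(0, 2, n)
            if events.sum() == 0 or len(np.unique(groups)) < 2:
                continue
            chi2, _ = logrank(times, events, groups)
            assert chi2 == pytest.approx(
                two_group_logrank_oracle(times, events, groups), abs=1e-9
            )

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        times = rng.exponential(3.0, 120)
        events = (rng.random(120) < 0.75).astype(int)
        groups = rng.integers(0, 3, 120)
        chi2, p = logrank(times, events, groups)
        res = multivariate_logrank_test(times, groups, events)
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-8)
        assert p == pytest.approx(res.p_value, rel=1e-8)

    def test_relabel_invariance(self, rng):
        times = rng.exponential(3.0, 60)
        events = (rng.random(60) < 0.8).astype(int)
        groups = rng.integers(0, 2, 60)
        chi2_a, _ = logrank(times, events, groups)
        chi2_b, _ = logrank(times, events, np.where(groups == 0, "x", "w"))
        assert chi2_a == pytest.approx(chi2_b)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank([1, 2, 3], [1, 1, 0], [0, 0, 0])

    def test_null_type_one_error(self, rng):
        # under the null both groups share the hazard; ~5% rejections
        n_rep, rejections = 400, 0
        for _ in range(n_rep):
            t, e = simulate_exponential_group(60, 0.2, rng, horizon=8.0)
            g = np.r_[np.zeros(30), np.ones(30)]
            _, p = logrank(t, e, g)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)


def _two_group_frame(rng, n_per_group, hr, base_rate=0.1, dropout=0.2):
    t0, e0 = simulate_exponential_group(n_per_group, base_rate, rng, dropout_rate=dropout)
    t1, e1 = simulate_exponential_group(n_per_group, base_rate * hr, rng, dropout_rate=dropout)
    return pd.DataFrame(
        {
            "os_years": np.r_[t0, t1],
            "os_event": np.r_[e0, e1],
            "group": ["ref"] * n_per_group + ["trt"] * n_per_group,
        }
    )


class TestCoxFit:
    def test_null_recovery(self, rng):
        df = _two_group_frame(rng, 2000, hr=1.0)
        fit = cox_fit(df, ["group"], reference_levels={"group": "ref"})
        hr = fit.effects.iloc[0]["hazard_ratio"]
        assert 0.9 <= hr <= 1.1

    @pytest.mark.parametrize("true_hr", [0.27, 0.45])
    def test_parameter_recovery(self, true_hr):
        rng = np.random.default_rng(20240915)
        df = _two_group_frame(rng, 2000, hr=true_hr)
        fit = cox_fit(df, ["group"], reference_levels={"group": "ref"})
        row = fit.effects.iloc[0]
        assert row["hazard_ratio"] == pytest.approx(true_hr, rel=0.10)
        assert row["ci95_low"] <= row["hazard_ratio"] <= row["ci95_high"]
        assert fit.c_index > 0.5

    def test_null_p_values_roughly_uniform(self, rng):
        # continuous covariate with zero effect: p ~ U(0,1)
        ps = []
        for _ in range(200):
            t, e = simulate_exponential_group(80, 0.2, rng, horizon=10.0)
            df = pd.DataFrame({"os_years": t, "os_event": e, "x": rng.normal(size=80)})
            ps.append(cox_fit(df, ["x"]).effects.iloc[0]["p_value"])
        ps = np.asarray(ps)
        assert np.mean(ps < 0.05) == pytest.approx(0.05, abs=0.05)
        assert np.mean(ps < 0.5) == pytest.approx(0.5, abs=0.12)

    def test_constant_covariate_rejected(self, rng):
        t, e = simulate_exponential_group(50, 0.2, rng)
        df = pd.DataFrame({"os_years": t, "os_event": e, "x": np.ones(50)})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["x"])

    def test_too_few_events_rejected(self):
        df = pd.DataFrame(
            {
                "os_years": [1.0, 2.0, 3.0, 4.0],
                "os_event": [0, 0, 0, 1],
                "a": [0.0, 1.0, 0.0, 1.0],
                "b": [1.0, 0.0, 1.0, 0.0],
            }
        )
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["a", "b"])

    def test_reference_level_direction(self, rng):
        df = _two_group_frame(rng, 500, hr=0.4)
        fit_fwd = cox_fit(df, ["group"], reference_levels={"group": "ref"})
        fit_rev = cox_fit(df, ["group"], reference_levels={"group": "trt"})
        assert fit_fwd.effects.iloc[0]["hazard_ratio"] == pytest.approx(
            1.0 / fit_rev.effects.iloc[0]["hazard_ratio"], rel=1e-6
        )

    def test_univariate_selection(self, rng):
        df = _two_group_frame(rng, 400, hr=0.3)
        df["noise"] = rng.normal(size=len(df))
        fits, selected = univariate_selection(df, ["group", "noise"])
        assert "group" in selected
        assert set(fits) == {"group", "noise"}


class TestCIndex:
    def test_perfect_inverse_order(self):
        times = np.array([1.0, 2, 3, 4, 5])
        risk = -times  # highest risk dies first
        assert c_index(risk, times, np.ones(5, dtype=int)) == 1.0

    def test_random_risk_near_half(self, rng):
        t, e = simulate_exponential_group(3000, 0.2, rng, horizon=10.0)
        assert c_index(rng.normal(size=3000), t, e) == pytest.approx(0.5, abs=0.03)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 7))
            times = np.round(rng.exponential(3.0, n), 1) + 0.1
            events = (rng.random(n) < 0.6).astype(int)
            risk = np.round(rng.normal(size=n), 1)
            try:
                expected = brute_force_c_index(risk, times, events)
            except ZeroDivisionError:
                with pytest.raises(ValueError):
                    c_index(risk, times, events)
                continue
            assert c_index(risk, times, events) == pytest.approx(expected)

    def test_no_comparable_pairs(self):
        with pytest.raises(ValueError, match="comparable"):
            c_index([1.0, 2.0], [1.0, 2.0], [0, 0])


class TestIauc:
    def test_independent_marker_near_half(self, rng):
        t, e = simulate_exponential_group(2000, 0.2, rng, horizon=8.0)
        assert iauc(rng.normal(size=2000), t, e) == pytest.approx(0.5, abs=0.03)

    def test_perfect_marker(self):
        times = np.linspace(0.5, 8.0, 40)
        risk = -times
        assert iauc(risk, times, np.ones(40, dtype=int)) == pytest.approx(1.0)

    def test_cross_implementation_oracle(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc as sk_cda

        risk = rng.normal(size=400)
        t_lat = rng.exponential(5 * np.exp(-0.7 * risk))
        c_lat = rng.uniform(0, 12, 400)
        times = np.minimum(t_lat, c_lat)
        events = (t_lat <= c_lat).astype(int)
        grid = np.quantile(times[events == 1], np.linspace(0.1, 0.8, 15))
        mine = cumulative_dynamic_auc(risk, times, events, grid)
        y = np.empty(400, dtype=[("e", bool), ("t", float)])
        y["e"], y["t"] = events.astype(bool), times
        theirs, _ = sk_cda(y, y, risk, grid)
        assert np.allclose(mine, theirs, atol=1e-10)

    def test_bounded_and_direction_agrees_with_c(self, rng):
        df = _two_group_frame(rng, 500, hr=0.4)
        risk = (df["group"] == "ref").astype(float).to_numpy()
        t = df["os_years"].to_numpy()
        e = df["os_event"].to_numpy()
        ia = iauc(risk, t, e)
        assert 0.5 < ia <= 1.0
        assert c_index(risk, t, e) > 0.5

    def test_no_events_before_horizon(self):
        with pytest.raises(ValueError, match="no events"):
            iauc([1.0, 2.0], [6.0, 7.0], [1, 1], horizon=5.0)

    def test_bad_horizon(self):
        with pytest.raises(ValueError):
            iauc([1.0], [1.0], [1], horizon=0.0)


class TestStratifiedKm:
    def _frame(self, rng, stage_effect=True):
        rows = []
        for stage in ("I", "II", "III"):
            for group, hr in (("lo", 1.0), ("hi", 0.3)):
                rate = 0.25 * (hr if stage_effect else 1.0)
                t, e = simulate_exponential_group(120, rate, rng, horizon=10.0)
                rows.append(pd.DataFrame({
                    "os_years": t, "os_event": e,
                    "stage": stage, "group": group,
                }))
        return pd.concat(rows, ignore_index=True)

    def test_detects_group_effect_in_stratum(self, rng):
        df = self._frame(rng)
        curves, p = stratified_km(df, "stage", "II", "group")
        assert set(curves) == {"lo", "hi"}
        assert p is not None and p < 0.05

    def test_empty_stratum_skipped(self, rng):
        curves, p = stratified_km(self._frame(rng), "stage", "IV", "group")
        assert curves == {} and p is None

    def test_single_group_stratum_skipped(self, rng):
        df = self._frame(rng)
        df = df[(df["stage"] != "I") | (df["group"] == "lo")]
        curves, p = stratified_km(df, "stage", "I", "group")
        assert set(curves) == {"lo"} and p is None

    def test_union_consistency_when_strata_ignored(self, rng):
        df = self._frame(rng)
        chi2_all, _ = logrank(df["os_years"], df["os_event"], df["group"])
        # pooled analysis must see the same subjects as the union of strata
        n_union = sum(
            len(df[df["stage"] == s]) for s in ("I", "II", "III")
        )
        assert n_union == len(df)
        assert chi2_all > 0
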