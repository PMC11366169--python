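import math

import numpy as np
import pandas as pd
import pytest

from imprintscan import classify, survival, synthetic
from imprintscan.survival import (
    cox_fit,
    cox_status_contrast,
    kaplan_scan,
    km_logrank,
    stratified_km_low_risk,
)

from conftest import tiny_catalog


def make_surv(times, events, prefix="S"):
    idx = [f"{prefix}{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events}, index=idx)


def cox_loghr_oracle(x, time, event, tol=1e-10):
    """Newton-Raphson on the Cox partial likelihood, single covariate, no ties."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    beta = 0.0
    for _ in range(100):
        score, info = 0.0, 0.0
        for i in np.where(event)[0]:
            risk = time >= time[i]
            w = np.exp(beta * x[risk])
            xbar = np.sum(w * x[risk]) / np.sum(w)
            x2bar = np.sum(w * x[risk] ** 2) / np.sum(w)
            score += x[i] - xbar
            info += x2bar - xbar**2
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    return beta


class TestKMLogrank:
    def test_identical_groups_null(self):
        times = list(range(1, 21))
        surv = make_surv(times + times, [1] * 40)
        status = pd.Series(["a"] * 20 + ["b"] * 20, index=surv.index)
        res, curves = km_logrank(status, surv)
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0, abs=1e-8)
        assert res.df == 1

    def test_curves_start_at_one_and_decrease(self):
        surv = make_surv([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 1])
        status = pd.Series(["a", "a", "a", "b", "b", "b"], index=surv.index)
        _, curves = km_logrank(status, surv)
        for curve in curves.values():
            assert curve.iloc[0]["survival"] == pytest.approx(1.0)
            assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_single_group_absent(self):
        surv = make_surv([1, 2, 3], [1, 1, 1])
        status = pd.Series(["a", "a", "a"], index=surv.index)
        with pytest.warns(UserWarning, match="<2 nonempty groups"):
            assert km_logrank(status, surv) is None

    def test_samples_without_survival_dropped(self):
        surv = make_surv([1, 2, 3, 4], [1, 1, 1, 1])
        status = pd.Series(["a", "a", "b", "b", "b"], index=list(surv.index) + ["extra"])
        res, _ = km_logrank(status, surv)
        assert sum(res.group_sizes.values()) == 4

    def test_power_under_simulated_hazard_ratio(self):
        # GOM simulated with HR 3 vs No change at n = 250: p < 0.05 in >= 90% of seeds
        hits = 0
        reps = 100
        for seed in range(reps):
            config = synthetic.SimulationConfig(
                seed=seed,
                n_tumours=250,
                n_controls=2,
                catalog=tiny_catalog(1),
                probes_per_dmr=1,
                dmr_specs={"DMR0": synthetic.DMRSimSpec({classify.GOM: 0.5})},
                survival=synthetic.SurvivalModel(
                    baseline_hazard=0.08,
                    status_log_hr={"DMR0": {classify.GOM: math.log(3.0)}},
                ),
            )
            bundle = synthetic.generate_cohort(config)
            status = bundle.truth_region.set_index("sample_id")["status"]
            surv = bundle.clinical.rename(
                columns={"os_time_years": "time", "os_event": "event"}
            )
            res, _ = km_logrank(status, surv)
            hits += res.p < 0.05
        assert hits >= 90


class TestCox:
    def test_matches_partial_likelihood_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(15, 31))
            x = (rng.random(n) < 0.5).astype(int)
            if x.sum() in (0, n):
                continue
            time = rng.exponential(1.0 / np.exp(0.5 * x))  # continuous: no ties
            event = rng.random(n) < 0.8
            if event.sum() < 3:
                continue
            surv = make_surv(time, event.astype(int))
            focal = pd.Series(x, index=surv.index)
            results = cox_fit(surv, focal)
            oracle = cox_loghr_oracle(x, time, event)
            assert math.log(results[0].hr) == pytest.approx(oracle, abs=1e-4)

    def test_constant_focal_rejected(self):
        surv = make_surv([1, 2, 3], [1, 1, 1])
        focal = pd.Series([1, 1, 1], index=surv.index)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(surv, focal)

    def test_constant_adjuster_dropped(self, rng):
        n = 60
        x = (rng.random(n) < 0.5).astype(int)
        surv = make_surv(rng.exponential(2, n), np.ones(n, dtype=int))
        focal = pd.Series(x, index=surv.index)
        adj = pd.DataFrame({"flat": np.zeros(n, dtype=int)}, index=surv.index)
        with pytest.warns(UserWarning, match="constant covariate"):
            results = cox_fit(surv, focal, adjusters=adj)
        assert [r.term for r in results] == ["focal"]

    def test_status_contrast_restricts_to_two_groups(self, rng):
        n = 90
        labels = rng.choice([classify.GOM, classify.INT_GOM, classify.NO_CHANGE], n)
        while len(set(labels)) < 3:
            labels = rng.choice([classify.GOM, classify.INT_GOM, classify.NO_CHANGE], n)
        surv = make_surv(rng.exponential(2, n), np.ones(n, dtype=int))
        status = pd.Series(labels, index=surv.index)
        results = cox_status_contrast(status, surv, classify.GOM)
        expected_n = int(pd.Series(labels).isin([classify.GOM, classify.NO_CHANGE]).sum())
        assert results[0].n == expected_n

    def test_dummy_contrast_keeps_all_groups(self, rng):
        n = 90
        labels = np.array(
            [classify.GOM, classify.LOM, classify.NO_CHANGE] * 30
        )
        surv = make_surv(rng.exponential(2, n), np.ones(n, dtype=int))
        status = pd.Series(labels, index=surv.index)
        results = cox_status_contrast(status, surv, classify.GOM, contrast="dummy")
        assert results[0].n == n
        assert {r.term for r in results} == {classify.GOM, classify.LOM}

    def test_ci_brackets_hr(self, rng):
        n = 120
        x = (rng.random(n) < 0.5).astype(int)
        time = rng.exponential(1.0 / np.exp(0.7 * x))
        surv = make_surv(time, np.ones(n, dtype=int))
        results = cox_fit(surv, pd.Series(x, index=surv.index))
        r = results[0]
        assert r.ci_low <= r.hr <= r.ci_high
        assert r.hr > 0


class TestKaplanScan:
    def test_constructed_separation(self):
        # early deaths have high expression; the scan should split the blocks
        n = 100
        expr = np.concatenate([np.linspace(10, 20, 50), np.linspace(30, 40, 50)])
        times = np.concatenate([np.linspace(5, 10, 50), np.linspace(0.5, 2, 50)])
        surv = make_surv(times, np.ones(n, dtype=int))
        expression = pd.Series(expr, index=surv.index)
        res = kaplan_scan(expression, surv)
        assert 20 < res.cutoff <= 30
        assert res.p_bonferroni < 0.01
        assert res.p_bonferroni == pytest.approx(
            min(1.0, res.p_raw * res.n_cutoffs_tested)
        )

    def test_identical_expression_absent(self):
        surv = make_surv([1, 2, 3, 4] * 5, [1] * 20)
        expression = pd.Series(np.ones(20), index=surv.index)
        with pytest.warns(UserWarning, match="no cutoff"):
            assert kaplan_scan(expression, surv) is None

    def test_bonferroni_identity(self, rng):
        surv = make_surv(rng.exponential(2, 40), np.ones(40, dtype=int))
        expression = pd.Series(rng.random(40), index=surv.index)
        res = kaplan_scan(expression, surv)
        assert res.p_bonferroni == pytest.approx(min(1.0, res.p_raw * res.n_cutoffs_tested))
        assert res.p_bonferroni >= res.p_raw
        assert res.n_cutoffs_tested == 40 - 2 * 8 + 1

    def test_invariant_to_monotone_transform(self, rng):
        surv = make_surv(rng.exponential(2, 40), np.ones(40, dtype=int))
        expression = pd.Series(rng.random(40), index=surv.index)
        res1 = kaplan_scan(expression, surv)
        res2 = kaplan_scan(np.exp(3 * expression), surv)
        assert res1.p_raw == pytest.approx(res2.p_raw)
        assert res1.n_cutoffs_tested == res2.n_cutoffs_tested
        assert res1.n_low == res2.n_low

    def test_min_group_respected(self, rng):
        surv = make_surv(rng.exponential(2, 30), np.ones(30, dtype=int))
        expression = pd.Series(rng.random(30), index=surv.index)
        res = kaplan_scan(expression, surv, min_group=10)
        assert res.n_low >= 10 and res.n_high >= 10


class TestStratifiedLowRisk:
    def _cohort(self, rng, effect_in_normal_only=True):
        n = 400
        idx = [f"S{i}" for i in range(n)]
        mycn = np.where(rng.random(n) < 0.25, "amplified", "not amplified")
        chr11 = np.where(rng.random(n) < 0.5, "11q deleted", "11q normal")
        status = np.where(rng.random(n) < 0.5, classify.GOM, classify.NO_CHANGE)
        rate = np.full(n, 0.1)
        if effect_in_normal_only:
            hit = (
                (status == classify.GOM)
                & (mycn == "not amplified")
                & (chr11 == "11q normal")
            )
            rate = np.where(hit, 0.6, rate)
        times = rng.exponential(1.0 / rate)
        clinical = pd.DataFrame({"mycn": mycn, "chr11": chr11}, index=idx)
        surv = pd.DataFrame(
            {"time": np.minimum(times, 12.0), "event": (times <= 12.0).astype(int)},
            index=idx,
        )
        return pd.Series(status, index=idx), surv, clinical

    def test_effect_confined_to_low_risk_stratum(self, rng):
        status, surv, clinical = self._cohort(rng)
        results = stratified_km_low_risk(status, surv, clinical)
        assert results["11q normal"].p < 0.05
        assert results["11q deleted"].p > 0.05

    def test_all_mycn_amplified_skipped(self, rng):
        status, surv, clinical = self._cohort(rng)
        clinical["mycn"] = "amplified"
        with pytest.warns(UserWarning, match="empty stratum"):
            results = stratified_km_low_risk(status, surv, clinical)
        assert results == {}

    def test_missing_columns_rejected(self, rng):
        status, surv, clinical = self._cohort(rng)
        with pytest.raises(KeyError):
            stratified_km_low_risk(status, surv, clinical.drop(columns="chr11"))
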