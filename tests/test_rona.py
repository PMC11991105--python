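"""Environmental pruning, per-SNP frequency models, RONA projections."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from islandadapt import (
    EnvPruneConfig,
    EnvTable,
    RonaConfig,
    compute_rona,
    fit_freq_env,
    prune_env,
)

from conftest import make_env, make_matrix


class TestPruneEnv:
    def test_identical_pair_lower_priority_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        env = make_env(np.column_stack([x, x]), variables=["A", "B"])
        kept, log = prune_env(env, EnvPruneConfig(priority={"A": 2, "B": 1}))
        assert kept == ["A"]
        assert log[0][0] == "B"

    def test_uncorrelated_set_untouched(self):
        rng = np.random.default_rng(1)
        env = make_env(rng.standard_normal((50, 4)))
        kept, log = prune_env(env, EnvPruneConfig())
        assert kept == env.variables and log == []

    def test_equal_priority_tie_drops_later_name(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(8)
        env = make_env(np.column_stack([x, x]), variables=["B1", "B2"])
        kept, _ = prune_env(env, EnvPruneConfig(priority={"B1": 1, "B2": 1}))
        assert kept == ["B1"]

    def test_planted_block_matches_bruteforce_oracle(self):
        """Three mutually correlated variables + two independent ones:
        the greedy result equals an independent re-implementation of the
        same rule using scipy.stats.pearsonr."""
        rng = np.random.default_rng(3)
        base = rng.standard_normal(40)
        block = np.column_stack(
            [base + 0.05 * rng.standard_normal(40) for _ in range(3)]
        )
        free = rng.standard_normal((40, 2))
        values = np.column_stack([block, free])
        names = ["C1", "C2", "C3", "F1", "F2"]
        env = make_env(values, variables=names)
        cfg = EnvPruneConfig(max_abs_corr=0.8)
        kept, _ = prune_env(env, cfg)

        # independent oracle: recompute correlations each round with pearsonr
        live = list(names)
        prio = {}
        for i, v in enumerate(names):
            rs = [
                abs(stats.pearsonr(values[:, i], values[:, j]).statistic)
                for j in range(len(names))
                if j != i
            ]
            prio[v] = -np.mean(rs)
        while True:
            worst = None
            for a, b in itertools.combinations(live, 2):
                r = stats.pearsonr(
                    values[:, names.index(a)], values[:, names.index(b)]
                ).statistic
                if abs(r) > cfg.max_abs_corr and (
                    worst is None or abs(r) > abs(worst[2])
                ):
                    worst = (a, b, r)
            if worst is None:
                break
            a, b, _ = worst
            if prio[a] < prio[b] or (prio[a] == prio[b] and a > b):
                live.remove(a)
            else:
                live.remove(b)
        assert kept == live
        assert set(kept) >= {"F1", "F2"}
        assert len([v for v in kept if v.startswith("C")]) == 1


def _line_fixture(slope=0.05, intercept=0.5, e=None):
    """Population frequencies exactly on a line against one variable.

    Defaults put every population frequency on an exact multiple of 1/8 so
    four diploids represent the line without rounding error.
    """
    e = np.array([-10.0, -5.0, 0.0, 5.0, 10.0]) if e is None else e
    freqs = intercept + slope * e
    # 4 diploids per pop whose mean dosage matches 2*freq exactly:
    # use dosage pairs summing to round(8*freq)
    cols = []
    for f in freqs:
        total = int(round(8 * f))
        d = [2] * (total // 2) + ([1] if total % 2 else []) + [0] * 4
        cols.append(d[:4])
    dosages = np.array(cols).reshape(-1, 1)
    pops = np.repeat([f"p{i}" for i in range(5)], 4)
    g = make_matrix(dosages.astype(np.int8), pops=pops)
    env = make_env(
        e.reshape(-1, 1),
        variables=["V1"],
        site_ids=[f"p{i}" for i in range(5)],
        future=(e + 2.0).reshape(-1, 1),
    )
    return g, env


class TestFitFreqEnv:
    def test_exact_line_recovered(self):
        g, env = _line_fixture()
        models = fit_freq_env(g, env, {"V1": np.array([0])})
        row = models.iloc[0]
        assert row["slope"] == pytest.approx(0.05, abs=1e-12)
        assert row["intercept"] == pytest.approx(0.5, abs=1e-12)
        assert row["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_frequencies_zero_slope(self):
        pops = np.repeat([f"p{i}" for i in range(5)], 2)
        g = make_matrix(np.ones((10, 1), dtype=np.int8), pops=pops)
        env = make_env(
            np.arange(5.0).reshape(-1, 1),
            variables=["V1"],
            site_ids=[f"p{i}" for i in range(5)],
        )
        models = fit_freq_env(g, env, {"V1": np.array([0])})
        assert models["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert models["r2"].iloc[0] == 0.0

    def test_individual_unit_uses_dosage_over_two(self):
        g, env = _line_fixture()
        cfg = RonaConfig(unit="individual")
        models = fit_freq_env(g, env, {"V1": np.array([0])}, cfg)
        assert models["slope"].iloc[0] == pytest.approx(0.05, abs=1e-12)

    def test_planted_slopes_within_two_se(self, gea_bundle):
        g, env, truth = gea_bundle
        by_var = {
            v: sub["snp_index"].to_numpy()
            for v, sub in truth.groupby("variable", sort=False)
        }
        models = fit_freq_env(g, env, by_var)
        merged = models.merge(
            truth, left_on=["variable", "snp_index"], right_on=["variable", "snp_index"]
        )
        cur = env.layer("current")
        n_ok = 0
        for _, row in merged.iterrows():
            e = cur[row["variable"]]
            z_sd = e.std(ddof=0)
            # slope is per raw env unit; truth slope is per sd unit
            b_true = row["slope_y"] / z_sd
            se = np.sqrt(0.25 / (2 * 20)) / np.sqrt(((e - e.mean()) ** 2).sum())
            n_ok += abs(row["slope_x"] - b_true) <= 2.5 * se
        assert n_ok / len(merged) >= 0.9

    def test_too_few_populations_rejected(self):
        pops = np.repeat(["a", "b"], 2)
        g = make_matrix(np.ones((4, 1), dtype=np.int8), pops=pops)
        env = make_env(np.array([[0.0], [1.0]]), variables=["V1"], site_ids=["a", "b"])
        with pytest.raises(ValueError, match="populations"):
            fit_freq_env(g, env, {"V1": np.array([0])})


class TestComputeRona:
    def test_future_equals_current_gives_zero(self):
        g, env = _line_fixture()
        env.values["same"] = env.values["current"].copy()
        models = fit_freq_env(g, env, {"V1": np.array([0])})
        rep = compute_rona(models, env, "same")
        assert np.allclose(rep.summary["rona"], 0.0)

    def test_single_snp_uniform_shift_analytic(self):
        """Perfect line f = 0.2 + 0.05 e, shift +2 -> RONA = 0.1 exactly."""
        g, env = _line_fixture()
        models = fit_freq_env(g, env, {"V1": np.array([0])})
        rep = compute_rona(
            models, env, "future", RonaConfig(clip_predictions=False)
        )
        assert np.allclose(rep.summary["rona"], 0.1, atol=1e-12)

    def test_matches_bruteforce_recomputation(self, gea_bundle):
        g, env, truth = gea_bundle
        by_var = {
            v: sub["snp_index"].to_numpy()
            for v, sub in truth.groupby("variable", sort=False)
        }
        cfg = RonaConfig()
        models = fit_freq_env(g, env, by_var, cfg)
        rep = compute_rona(models, env, "SSP585", cfg)
        for _, row in rep.summary.iterrows():
            sub = models[models["variable"] == row["variable"]]
            i = env.site_ids.index(row["population"])
            jv = env.variables.index(row["variable"])
            num = den = 0.0
            for _, m in sub.iterrows():
                fc = min(max(m["intercept"] + m["slope"] * env.values["current"][i, jv], 0.0), 1.0)
                ff = min(max(m["intercept"] + m["slope"] * env.values["SSP585"][i, jv], 0.0), 1.0)
                num += m["r2"] * abs(ff - fc)
                den += m["r2"]
            assert row["rona"] == pytest.approx(num / den, abs=1e-12)

    def test_affine_invariance_of_environment_units(self, gea_bundle):
        """Rescaling e -> a*e + c in all layers leaves RONA unchanged."""
        g, env, truth = gea_bundle
        by_var = {
            v: sub["snp_index"].to_numpy()
            for v, sub in truth.groupby("variable", sort=False)
        }
        cfg = RonaConfig()
        base = compute_rona(fit_freq_env(g, env, by_var, cfg), env, "SSP126", cfg)
        scaled = EnvTable(
            site_ids=list(env.site_ids),
            variables=list(env.variables),
            values={k: 3.7 * v - 11.0 for k, v in env.values.items()},
        )
        again = compute_rona(
            fit_freq_env(g, scaled, by_var, cfg), scaled, "SSP126", cfg
        )
        np.testing.assert_allclose(
            base.summary["rona"], again.summary["rona"], atol=1e-10
        )

    def test_monotone_in_shift_until_clipped(self):
        g, env = _line_fixture()
        models = fit_freq_env(g, env, {"V1": np.array([0])})
        e = env.values["current"]
        prev = -1.0
        values = []
        for shift in (0.5, 1.0, 2.0, 4.0, 100.0, 200.0):
            env.values["s"] = e + shift
            rep = compute_rona(models, env, "s")
            v = rep.summary["rona"].mean()
            assert v >= prev - 1e-12
            prev = v
            values.append(v)
        # eventually saturates once predictions hit the [0, 1] clip bounds
        assert values[-1] == pytest.approx(values[-2], abs=1e-9)

    def test_weighted_rona_between_min_and_max_snp_shift(self, gea_bundle):
        g, env, truth = gea_bundle
        v = truth["variable"].iloc[0]
        idx = truth[truth["variable"] == v]["snp_index"].to_numpy()
        cfg = RonaConfig()
        models = fit_freq_env(g, env, {v: idx}, cfg)
        rep = compute_rona(models, env, "SSP585", cfg)
        jv = env.variables.index(v)
        for i, p in enumerate(env.site_ids):
            ec, ef = env.values["current"][i, jv], env.values["SSP585"][i, jv]
            shifts = [
                abs(
                    np.clip(m["intercept"] + m["slope"] * ef, 0, 1)
                    - np.clip(m["intercept"] + m["slope"] * ec, 0, 1)
                )
                for _, m in models.iterrows()
            ]
            val = rep.value(p, v, "SSP585")
            assert min(shifts) - 1e-12 <= val <= max(shifts) + 1e-12

    def test_population_and_individual_units_agree_on_deterministic_data(self):
        g, env = _line_fixture()
        for unit in ("population", "individual"):
            cfg = RonaConfig(unit=unit, clip_predictions=False)
            models = fit_freq_env(g, env, {"V1": np.array([0])}, cfg)
            rep = compute_rona(models, env, "future", cfg, g)
            assert np.allclose(rep.summary["rona"], 0.1, atol=1e-12)

    def test_missing_scenario_rejected(self):
        g, env = _line_fixture()
        models = fit_freq_env(g, env, {"V1": np.array([0])})
        with pytest.raises(ValueError, match="scenario"):
            compute_rona(models, env, "nope")
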