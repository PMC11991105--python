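"""Latent factors, association tests, calibration, q-values, hotspots."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from islandadapt import (
    GeaConfig,
    StructureSimConfig,
    candidate_union,
    estimate_latent_factors,
    fit_association,
    hotspot_windows,
    qvalues,
    sim_structured_genotypes,
)

from conftest import make_env, make_matrix


class TestLatentFactors:
    def test_k_zero_empty(self, structured_matrix):
        U = estimate_latent_factors(structured_matrix, 0)
        assert U.shape == (structured_matrix.n_samples, 0)

    def test_k_too_large_rejected(self, structured_matrix):
        with pytest.raises(ValueError):
            estimate_latent_factors(structured_matrix, structured_matrix.n_samples)

    def test_two_deme_factor_separates_demes(self):
        g = sim_structured_genotypes(
            StructureSimConfig(n_pops=2, n_per_pop=20, n_snps=5000, fst=0.2, seed=13)
        )
        U = estimate_latent_factors(g, 1)
        label = (g.pop_of_sample == g.populations[0]).astype(float)
        r = np.corrcoef(U[:, 0], label)[0, 1]
        assert abs(r) > 0.9

    def test_duplicated_samples_get_equal_factors(self, structured_matrix):
        g = structured_matrix
        dup = g.take_samples(np.repeat(np.arange(g.n_samples), 2))
        U = estimate_latent_factors(dup, 2)
        np.testing.assert_allclose(U[0::2], U[1::2], atol=1e-8)

    def test_deterministic_signs(self, structured_matrix):
        a = estimate_latent_factors(structured_matrix, 3)
        b = estimate_latent_factors(structured_matrix, 3)
        np.testing.assert_array_equal(a, b)
        for k in range(3):
            assert a[np.argmax(np.abs(a[:, k])), k] > 0


class TestQvalues:
    def test_bh_fallback_hand_computed(self):
        q = qvalues(np.array([0.01, 0.02, 0.03, 0.9]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.9], atol=1e-12)

    def test_all_ones(self):
        assert np.all(qvalues(np.ones(10)) == 1.0)
        assert np.all(qvalues(np.ones(500)) == 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_in_p(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(1000)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            float,
            st.integers(min_value=1, max_value=400),
            elements=st.floats(0.0, 1.0),
        )
    )
    def test_qvalues_bounded_and_monotone_property(self, p):
        q = qvalues(p)
        assert np.all((q >= 0.0) & (q <= 1.0))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_storey_pi0_less_than_one_with_signal(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.random(900), rng.beta(0.1, 10, 100)])
        q = qvalues(p)
        bh = qvalues(p, pi0=1.0)
        assert np.all(q <= bh + 1e-12)  # pi0 < 1 shrinks q


class TestFitAssociation:
    def _env_for(self, g, values, name="V1"):
        pops = g.populations
        return make_env(
            np.asarray(values, dtype=float).reshape(-1, 1),
            variables=[name],
            site_ids=pops,
        )

    def test_perfect_association_tiny_p(self):
        rng = np.random.default_rng(0)
        e_site = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        pops = np.repeat([f"p{i}" for i in range(5)], 6)
        dos = np.clip(np.round(1.0 + 0.5 * np.repeat(e_site, 6)), 0, 2)
        extra = rng.integers(0, 3, (30, 20))
        g = make_matrix(
            np.column_stack([dos, extra]).astype(np.int8), pops=pops
        )
        env = self._env_for(g, e_site)
        res = fit_association(g, env, cfg=GeaConfig(K=0, calibrate=False))
        assert res.table["p_raw"].iloc[0] < 1e-10

    def test_k0_equals_closed_form_simple_regression(self):
        rng = np.random.default_rng(2)
        pops = np.repeat([f"p{i}" for i in range(5)], 4)
        g = make_matrix(rng.integers(0, 3, (20, 50)).astype(np.int8), pops=pops)
        e_site = rng.standard_normal(5)
        env = self._env_for(g, e_site)
        res = fit_association(g, env, cfg=GeaConfig(K=0, calibrate=False))
        e = np.repeat(e_site, 4)
        e_std = (e - e.mean()) / e.std()
        n = 20
        for j in range(50):
            y = g.dosages[:, j].astype(float)
            slope, intercept, r, p, se = stats.linregress(e_std, y)
            assert res.table["effect"].iloc[j] == pytest.approx(slope, abs=1e-10)
            assert res.table["p_raw"].iloc[j] == pytest.approx(p, abs=1e-10)

    def test_null_calibrated_p_uniform(self):
        """Unstructured data, env independent of genotype: calibrated
        p-values are approximately uniform (KS < 0.02 at 10^4 SNPs)."""
        g = sim_structured_genotypes(
            StructureSimConfig(
                n_pops=5, n_per_pop=12, n_snps=10_000, fst=1e-4, seed=31
            )
        )
        rng = np.random.default_rng(31)
        env = self._env_for(g, rng.standard_normal(5))
        res = fit_association(g, env, cfg=GeaConfig(K=2))
        ks = stats.kstest(res.table["p_cal"], "uniform").statistic
        assert ks < 0.02

    def test_structured_null_inflation_then_calibration(self):
        """Deme structure + env aligned with deme means inflates raw z;
        lambda > 1 before calibration and exactly 1 after."""
        g = sim_structured_genotypes(
            StructureSimConfig(n_pops=5, n_per_pop=12, n_snps=5000, fst=0.1, seed=17)
        )
        env = self._env_for(g, np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        res = fit_association(g, env, cfg=GeaConfig(K=0))
        lam_raw = res.inflation["V1"]
        assert lam_raw > 1.0
        z2_cal = stats.chi2.isf(res.table["p_cal"], df=1)
        lam_re = np.median(z2_cal) / stats.chi2.ppf(0.5, 1)
        assert abs(lam_re - 1.0) < 0.1

    def test_constant_env_rejected(self, structured_matrix):
        env = self._env_for(structured_matrix, np.zeros(5), name="FLAT")
        with pytest.raises(ValueError, match="FLAT"):
            fit_association(structured_matrix, env, cfg=GeaConfig(K=0))

    def test_pooled_qvalues_rank_across_variables(self, structured_matrix):
        g = structured_matrix.take_snps(np.arange(300))
        rng = np.random.default_rng(6)
        env = make_env(
            rng.standard_normal((5, 2)), variables=["V1", "V2"],
            site_ids=g.populations,
        )
        res = fit_association(g, env, cfg=GeaConfig(K=1, pool_qvalues=True))
        expected = qvalues(res.table["p_cal"].to_numpy())
        np.testing.assert_allclose(res.table["q"], expected, atol=1e-12)

    def test_zero_variance_snp_p_one(self):
        pops = np.repeat(["a", "b", "c"], 4)
        dos = np.ones((12, 3), dtype=np.int8)
        dos[:, 1] = np.random.default_rng(0).integers(0, 3, 12)
        g = make_matrix(dos, pops=pops)
        env = make_env(
            np.array([[0.0], [1.0], [2.0]]), variables=["V1"], site_ids=["a", "b", "c"]
        )
        res = fit_association(g, env, cfg=GeaConfig(K=0, calibrate=False))
        assert res.table["p_raw"].iloc[0] == 1.0
        assert res.table["p_raw"].iloc[2] == 1.0


class TestCandidatesAndHotspots:
    def _result_with(self, g, flags_by_var):
        import pandas as pd

        from islandadapt.gea import GeaResult

        frames = []
        for v, idx in flags_by_var.items():
            cand = np.zeros(g.n_snps, bool)
            cand[idx] = True
            frames.append(
                pd.DataFrame(
                    {
                        "variable": v,
                        "snp_index": np.arange(g.n_snps),
                        "chrom": g.chrom,
                        "pos": g.pos,
                        "candidate": cand,
                    }
                )
            )
        return GeaResult(
            table=pd.concat(frames, ignore_index=True),
            inflation={},
            U=np.empty((g.n_samples, 0)),
            fdr_threshold=0.01,
        )

    def test_union_disjoint_and_identical(self, structured_matrix):
        g = structured_matrix
        res = self._result_with(g, {"A": [0, 1, 2], "B": [10, 11, 12, 13]})
        union, counts = candidate_union(res)
        assert len(union) == 7 and counts == {"A": 3, "B": 4}
        res2 = self._result_with(g, {"A": [5, 6], "B": [5, 6]})
        union2, counts2 = candidate_union(res2)
        assert len(union2) == 2 and counts2 == {"A": 2, "B": 2}

    def test_union_matches_bruteforce_on_random_sets(self, structured_matrix):
        rng = np.random.default_rng(4)
        sets = {
            v: rng.choice(structured_matrix.n_snps, size=30, replace=False)
            for v in "ABC"
        }
        res = self._result_with(structured_matrix, sets)
        union, _ = candidate_union(res)
        brute = set()
        for idx in sets.values():
            brute |= set(int(i) for i in idx)
        assert set(int(i) for i in union) == brute

    def test_hotspot_counts_match_bruteforce(self, structured_matrix):
        g = structured_matrix
        rng = np.random.default_rng(9)
        cand = rng.choice(g.n_snps, size=200, replace=False)
        windows, per_chrom, r, p = hotspot_windows(cand, g, window=1_000_000)
        for _, row in windows.iterrows():
            n = sum(
                1
                for i in cand
                if g.chrom[i] == row["chrom"]
                and row["start"] < g.pos[i] <= row["end"]
            )
            assert n == row["count"]
        assert per_chrom["count"].sum() == 200

    def test_all_candidates_in_one_window(self):
        pos = np.arange(1, 21) * 10
        g = make_matrix(np.zeros((4, 20), dtype=np.int8), pos=pos)
        windows, per_chrom, _, _ = hotspot_windows(np.arange(20), g, window=1_000_000)
        assert windows["count"].iloc[0] == 20
        assert windows["count"].sum() == 20

    def test_uniform_placement_fits_poisson(self, structured_matrix):
        g = structured_matrix
        rng = np.random.default_rng(23)
        cand = rng.choice(g.n_snps, size=400, replace=False)
        windows, _, _, _ = hotspot_windows(cand, g, window=1_000_000)
        counts = windows["count"].to_numpy()
        mean = counts.mean()
        # chi-square GOF against equal-mean Poisson
        edges = [-0.5, mean - 2, mean, mean + 2, np.inf]
        obs, _ = np.histogram(counts, bins=edges)
        pk = np.diff([stats.poisson.cdf(e, mean) for e in edges])
        pk = np.maximum(pk, 1e-12)
        chi2 = ((obs - len(counts) * pk) ** 2 / (len(counts) * pk)).sum()
        assert stats.chi2.sf(chi2, df=len(obs) - 1) > 0.01
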