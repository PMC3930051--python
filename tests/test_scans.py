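"""Selection scans: F_ST estimation, outlier envelopes, the Bayesian
decomposition, the logistic association scan, and consensus reporting."""

import numpy as np
import pandas as pd
import pytest

from aflpscape.datatypes import BandMatrix
from aflpscape.estimators import band_frequencies
from aflpscape.scans import (
    ScanConfig,
    bayescan_scan,
    consensus_outliers,
    dominant_fst,
    fdist_scan,
    locus_trait_correlation,
    sam_scan,
)
from aflpscape.simulate import (
    SimulationConfig,
    simulate_band_matrix,
    simulate_hierarchical_frequencies,
)
from tests.conftest import neutral_config


def _neutral_matrix(seed, **kw):
    cfg = neutral_config(seed, **kw)
    fr = simulate_hierarchical_frequencies(cfg)
    return simulate_band_matrix(fr, cfg)


class TestDominantFst:
    def test_identical_populations_near_zero(self):
        m = _neutral_matrix(1, fst=1e-6, n_ind=200, n_loci=300)
        df = dominant_fst(m)
        assert np.quantile(np.abs(df["fst"]), 0.99) < 0.02
        assert abs(df["fst"].mean()) < 0.005

    def test_recovers_planted_differentiation(self):
        m = _neutral_matrix(2, fst=0.10, n_loci=500, n_ind=50)
        df = dominant_fst(m)
        assert df.attrs["mean_fst"] == pytest.approx(0.10, abs=0.02)

    def test_fixed_difference_is_extreme(self):
        # fixed opposite phenotypes; large samples so the Bayesian
        # frequency estimates approach 0/1
        vals = np.vstack([np.ones((150, 30)), np.zeros((150, 30))])
        vals[:, 1:] = np.random.default_rng(0).random((300, 29)) < 0.5
        m = BandMatrix(vals, [f"i{k}" for k in range(300)],
                       ["A"] * 150 + ["B"] * 150, [f"L{j}" for j in range(30)])
        df = dominant_fst(m).set_index("locus")
        assert df.loc["L0", "fst"] > 0.9

    def test_monomorphic_loci_excluded(self):
        m = _neutral_matrix(3, n_loci=100)
        m.values[:, 0] = 1.0  # force one monomorphic locus
        df = dominant_fst(m)
        assert "L001" not in set(df["locus"])
        assert df.attrs["n_excluded_monomorphic"] >= 1


class TestFdistScan:
    def test_trimming_lowers_target_mean(self):
        m = _neutral_matrix(4, n_loci=400)
        fd = fdist_scan(m, ScanConfig(n_sim=4000), seed=0)
        rounds = fd.attrs["rounds"]
        if len(rounds) > 1:
            means = [r["target_mean_fst"] for r in rounds]
            assert all(a >= b for a, b in zip(means, means[1:]))

    def test_seed_reproducibility(self):
        m = _neutral_matrix(5, n_loci=150)
        a = fdist_scan(m, ScanConfig(n_sim=3000), seed=9)
        b = fdist_scan(m, ScanConfig(n_sim=3000), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_lower_tail_not_flagged(self):
        m = _neutral_matrix(6, n_loci=200)
        fd = fdist_scan(m, ScanConfig(n_sim=3000), seed=1)
        # flags are upper-tail only; lower-tail mass is informational
        flagged = fd.loc[fd["fdist_candidate"]]
        assert np.all(flagged["fdist_p"] <= 0.01)


class TestBayescan:
    def test_prior_odds_zero_forbids_inclusion(self):
        m = _neutral_matrix(7, n_loci=60)
        cfg = ScanConfig(chain_length=600, burn_in=200, prior_inclusion_odds=0.0)
        bs = bayescan_scan(m, cfg, seed=0)
        assert np.all(bs["pip"] == 0.0)

    def test_qvalues_monotone_in_pip(self):
        m = _neutral_matrix(8, n_loci=80)
        cfg = ScanConfig(chain_length=1500, burn_in=500)
        bs = bayescan_scan(m, cfg, seed=1)
        srt = bs.sort_values("pip", ascending=False)
        assert np.all(np.diff(srt["qvalue"]) >= -1e-12)

    def test_strong_outlier_detected(self):
        # one locus with F_ST ~ 0.4-0.5 against a 0.07 background: the
        # alternating 0.18/0.82 spread realizes that differentiation at
        # samples of 30 per population
        hits = 0
        for rep in range(5):
            cfg = neutral_config(40 + rep, n_loci=120, fst=0.07, n_ind=30)
            fr = simulate_hierarchical_frequencies(cfg)
            fr.pop_freq[:, 0] = np.where(np.arange(9) % 2 == 0, 0.18, 0.82)
            m = simulate_band_matrix(fr, cfg)
            bs = bayescan_scan(
                m, ScanConfig(chain_length=4000, burn_in=1500), seed=rep
            ).set_index("locus")
            hits += bs.loc["L001", "pip"] > 0.9 and bs.loc["L001", "qvalue"] <= 0.05
        assert hits >= 4


class TestSamScan:
    def _predictors(self, pops, values):
        return pd.DataFrame({"population": pops, "x": values})

    def test_family_size_and_threshold(self):
        m = _neutral_matrix(9, n_loci=250)
        df = dominant_fst(m)
        pops = [f"P{i}" for i in range(1, 10)]
        preds = pd.DataFrame({
            "population": pops,
            "PC1": np.linspace(-1, 1, 9),
            "PC2": np.linspace(1, -1, 9) ** 2,
        })
        sam = sam_scan(m, preds, alpha=0.01)
        assert sam.attrs["n_models"] == 2 * len(df)
        assert sam.attrs["bonferroni_threshold"] == pytest.approx(0.01 / (2 * len(df)))

    def test_strong_cline_rejected_by_both_tests(self):
        # deterministic frequencies 0.1/0.5/0.9 along the predictor
        rng = np.random.default_rng(3)
        n = 200
        bands = np.concatenate([
            rng.random(n) < 0.1, rng.random(n) < 0.5, rng.random(n) < 0.9,
        ]).astype(float)[:, None]
        filler = (rng.random((3 * n, 4)) < 0.5).astype(float)
        vals = np.hstack([bands, filler])
        m = BandMatrix(vals, [f"i{k}" for k in range(3 * n)],
                       ["A"] * n + ["B"] * n + ["C"] * n,
                       [f"L{j}" for j in range(5)])
        preds = self._predictors(["A", "B", "C"], [-1.0, 0.0, 1.0])
        sam = sam_scan(m, preds).set_index("locus")
        assert sam.loc["L0", "wald_p"] < 1e-5
        assert sam.loc["L0", "g_p"] < 1e-5

    def test_g_statistic_nonnegative_and_order_invariant(self):
        m = _neutral_matrix(10, n_loci=60)
        preds = self._predictors([f"P{i}" for i in range(1, 10)],
                                 np.linspace(-1, 1, 9))
        sam = sam_scan(m, preds)
        assert np.all(sam["g_stat"] >= 0)
        perm = np.random.default_rng(0).permutation(m.n_loci)
        sam2 = sam_scan(m.subset_loci(perm), preds)
        merged = sam.merge(sam2, on=["locus", "predictor"], suffixes=("", "_p"))
        assert (merged["significant"] == merged["significant_p"]).all()

    def test_constant_predictor_rejected(self):
        m = _neutral_matrix(11, n_loci=30)
        preds = self._predictors([f"P{i}" for i in range(1, 10)], np.ones(9))
        with pytest.raises(ValueError, match="constant"):
            sam_scan(m, preds)

    def test_familywise_error_controlled(self):
        # band truly independent of predictor (no drift either, so
        # individuals are exchangeable): any significant call is a
        # family-wise error; its rate stays at or below alpha
        errors = 0
        reps = 60
        for rep in range(reps):
            m = _neutral_matrix(100 + rep, n_loci=80, n_ind=10, fst=0.0)
            preds = self._predictors([f"P{i}" for i in range(1, 10)],
                                     np.linspace(-1, 1, 9))
            sam = sam_scan(m, preds, alpha=0.01)
            errors += sam["significant"].any()
        assert errors / reps <= 0.05

    def test_matches_statsmodels_logit(self):
        import statsmodels.api as sm
        m = _neutral_matrix(12, n_loci=40, n_ind=30)
        x = np.linspace(-1, 1, 9)
        preds = self._predictors([f"P{i}" for i in range(1, 10)], x)
        sam = sam_scan(m, preds).set_index("locus")
        xcol = np.array([x[int(p[1]) - 1] for p in m.population_ids])
        checked = 0
        for j, loc in enumerate(m.locus_names):
            if loc not in sam.index or sam.loc[loc, "unstable"]:
                continue
            y = m.values[:, j]
            ok = ~np.isnan(y)
            fit = sm.Logit(y[ok], sm.add_constant(xcol[ok])).fit(disp=0)
            assert sam.loc[loc, "slope"] == pytest.approx(fit.params[1], abs=1e-5)
            checked += 1
            if checked >= 10:
                break
        assert checked >= 5


class TestConsensus:
    def _fake(self, loci, cands, fst=None):
        df = pd.DataFrame({"locus": loci,
                           "m_candidate": [l in cands for l in loci]})
        if fst is not None:
            df["fst"] = fst
        return df

    def test_single_method_passthrough(self):
        df = self._fake(["a", "b", "c"], {"b"})
        out = consensus_outliers({"m": df})
        assert list(out["locus"]) == ["b"]
        assert out["n_methods"].tolist() == [1]

    def test_disjoint_methods_all_count_one(self):
        out = consensus_outliers({
            "m1": self._fake(["a", "b", "c"], {"a"}),
            "m2": self._fake(["a", "b", "c"], {"c"}),
        })
        assert set(out["locus"]) == {"a", "c"}
        assert out["n_methods"].tolist() == [1, 1]

    def test_detection_percentages(self):
        out = consensus_outliers({
            "m1": self._fake([f"l{i}" for i in range(100)], {"l1", "l2"}),
        })
        assert out.attrs["percent_detected"]["m1"] == pytest.approx(2.0)


class TestLocusTraitCorrelation:
    def _freqs(self, mat, seed=0):
        m = _neutral_matrix(seed, n_loci=mat)
        return band_frequencies(m)

    def test_exact_trait_yields_r_one(self):
        f = self._freqs(20, seed=13)
        t = pd.DataFrame({
            "population": f.populations,
            "trait_a": f.freq[:, 0],
            "trait_b": np.random.default_rng(1).normal(size=9),
        })
        rep = locus_trait_correlation(f, [f.loci[0]], {"exp": t})
        top = rep.iloc[0]
        assert top["trait"] == "trait_a"
        assert abs(top["r"]) == pytest.approx(1.0, abs=1e-9)
        assert top["significant"]

    def test_duplicated_trait_pruned(self):
        f = self._freqs(20, seed=14)
        rng = np.random.default_rng(2)
        base = rng.normal(size=9)
        t = pd.DataFrame({
            "population": f.populations,
            "t1": base, "t2": base.copy(),
            "t3": rng.normal(size=9),
        })
        rep = locus_trait_correlation(f, [f.loci[0]], {"exp": t})
        assert len(set(rep["trait"])) == 2  # one of the twins removed

    def test_zero_variance_trait_dropped(self):
        f = self._freqs(20, seed=15)
        t = pd.DataFrame({
            "population": f.populations,
            "flat": np.ones(9),
            "ok": np.random.default_rng(3).normal(size=9),
        })
        with pytest.warns(UserWarning, match="zero variance"):
            rep = locus_trait_correlation(f, [f.loci[0]], {"exp": t})
        assert "flat" not in set(rep["trait"])

    def test_planted_trait_locus_recovered(self, default_dataset):
        ds = default_dataset
        f = band_frequencies(ds.band_matrix)
        loc = f.loci[ds.truth["trait_locus"]]
        rep = locus_trait_correlation(f, [loc], ds.phenotypes)
        hit = rep[(rep["locus"] == loc) & (rep["trait"] == "stem_trichomes")
                  & (rep["experiment"] == "net_house")]
        assert len(hit) == 1 and hit.iloc[0]["significant"]
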