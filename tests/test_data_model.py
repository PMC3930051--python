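"""Containers, I/O round trips, and the primitive estimators."""

import numpy as np
import pytest

from aflpscape.datatypes import BandMatrix
from aflpscape.estimators import (
    band_frequencies,
    estimate_null_allele_freq,
    genotyping_error_rate,
    null_freq_bayes,
    ssa_from_hmc,
)
from aflpscape.io import BandMatrixParseError, read_band_matrix, write_band_matrix
from aflpscape.simulate import SimulationConfig, simulate_band_matrix, simulate_hierarchical_frequencies


def _riemann_posterior_mean_q(absent, n, grid=200_001):
    """Independent fine-grid oracle: posterior mean of q under a uniform
    prior with Binomial(n, q^2) likelihood for the absent count."""
    q = np.linspace(0.0, 1.0, grid)
    loglik = 2 * absent * np.log(np.maximum(q, 1e-300)) + (n - absent) * np.log1p(
        -np.minimum(q ** 2, 1 - 1e-16)
    )
    w = np.exp(loglik - loglik.max())
    return float(np.trapezoid(q * w, q) / np.trapezoid(w, q))


class TestBandMatrixIO:
    def test_round_trip_identity(self, tiny_matrix, tmp_path):
        p = tmp_path / "m.csv"
        write_band_matrix(tiny_matrix, p)
        back = read_band_matrix(p)
        np.testing.assert_array_equal(back.values, tiny_matrix.values)
        assert back.individual_ids == tiny_matrix.individual_ids
        assert back.population_ids == tiny_matrix.population_ids
        assert back.locus_names == tiny_matrix.locus_names

    def test_round_trip_with_missing_and_replicates(self, tmp_path):
        vals = np.array([[1, 0], [0, np.nan], [1, 1], [1, 0]], dtype=float)
        m = BandMatrix(vals, ["a", "b", "c", "a_rep"], ["P", "P", "P", "P"],
                       ["54GA250", "55TG110"], [None, None, None, "a"])
        p = tmp_path / "m.csv"
        write_band_matrix(m, p)
        back = read_band_matrix(p)
        assert np.isnan(back.values[1, 1])
        assert back.replicate_of == [None, None, None, "a"]
        assert back.locus_names == ["54GA250", "55TG110"]  # names verbatim

    def test_genalex_dialect_round_trip(self, tiny_matrix, tmp_path):
        p = tmp_path / "m.csv"
        write_band_matrix(tiny_matrix, p, dialect="genalex")
        back = read_band_matrix(p, dialect="genalex")
        np.testing.assert_array_equal(back.values, tiny_matrix.values)

    @pytest.mark.parametrize("rows,msg", [
        ("individual,population,L1\nx,P,1\ny,P,1,0\n", "ragged"),
        ("individual,population,L1\nx,P,2\nz,P,0\n", "unknown band code"),
        ("individual,population,L1\nx,P,1\nx,P,0\n", "duplicate"),
    ])
    def test_parse_errors_carry_line_numbers(self, tmp_path, rows, msg):
        p = tmp_path / "bad.csv"
        p.write_text(rows)
        with pytest.raises(BandMatrixParseError, match=msg):
            read_band_matrix(p)

    def test_missing_cell_reduces_n_eff(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "individual,population,L1\n"
            "a,P,1\nb,P,1\nc,P,-9\nd,P,1\ne,P,0\n"
        )
        f = band_frequencies(read_band_matrix(p))
        assert f.n_eff[0, 0] == 4
        assert f.freq[0, 0] == pytest.approx(0.75)

    def test_large_matrix_parses_quickly(self, tmp_path):
        import time
        cfg = SimulationConfig(seed=4, n_replicate_pairs=0, n_individuals_per_pop=15)
        fr = simulate_hierarchical_frequencies(cfg)
        m = simulate_band_matrix(fr, cfg)
        p = tmp_path / "big.csv"
        write_band_matrix(m, p)
        t0 = time.time()
        back = read_band_matrix(p)
        assert time.time() - t0 < 1.0
        assert back.values.shape == (135, 229)


class TestBandFrequencies:
    def test_all_present_gives_one(self):
        m = BandMatrix(np.ones((4, 3)), list("abcd"), ["P"] * 4, ["l1", "l2", "l3"])
        f = band_frequencies(m)
        assert np.all(f.freq == 1.0)

    def test_row_permutation_invariance(self, tiny_matrix):
        f = band_frequencies(tiny_matrix)
        perm = [2, 0, 1, 5, 3, 4]
        m2 = BandMatrix(
            tiny_matrix.values[perm],
            [tiny_matrix.individual_ids[i] for i in perm],
            [tiny_matrix.population_ids[i] for i in perm],
            tiny_matrix.locus_names,
        )
        f2 = band_frequencies(m2)
        np.testing.assert_allclose(f.freq, f2.freq)

    def test_frequencies_recover_hwe_band_probability(self):
        # band frequency converges to 1 - q^2 at large n
        cfg = SimulationConfig(
            n_clusters=1, pops_per_cluster=2, n_admixed=0,
            n_individuals_per_pop=2000, n_loci=300, F_CT=0.0, F_SC=0.0,
            n_selected_loci=0, missing_rate=0.0, n_replicate_pairs=0, seed=9,
        )
        fr = simulate_hierarchical_frequencies(cfg)
        m = simulate_band_matrix(fr, cfg)
        f = band_frequencies(m)
        expected = 1.0 - (1.0 - fr.pop_freq) ** 2
        assert np.max(np.abs(f.freq - expected)) < 0.05
        assert np.mean(np.abs(f.freq - expected)) < 0.02


class TestNullAlleleFrequency:
    def test_sqrt_perfect_square(self):
        assert estimate_null_allele_freq(25, 100, "sqrt") == pytest.approx(0.5)

    def test_sqrt_zero_absent(self):
        assert estimate_null_allele_freq(0, 15, "sqrt") == 0.0

    def test_n_zero_is_error(self):
        with pytest.raises(ValueError):
            estimate_null_allele_freq(0, 0)

    @pytest.mark.parametrize("absent,n", [(5, 15), (0, 15), (15, 15), (1, 4), (40, 100)])
    def test_bayes_matches_quadrature_oracle(self, absent, n):
        got = estimate_null_allele_freq(absent, n, "bayes_uniform")
        oracle = _riemann_posterior_mean_q(absent, n)
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_bayes_strictly_interior(self):
        a = np.arange(1, 15)
        q = null_freq_bayes(a, 15)
        assert np.all(q > 0) and np.all(q < 1)

    def test_bayes_converges_to_sqrt(self):
        n = 100_000
        absent = 25_000
        bayes = estimate_null_allele_freq(absent, n, "bayes_uniform")
        assert bayes == pytest.approx(0.5, abs=1e-3)


class TestGenotypingErrorRate:
    def _with_replicate(self, flip_first):
        vals = np.vstack([np.ones((3, 229)), np.ones((1, 229))])
        if flip_first:
            vals[3, 0] = 0.0
        return BandMatrix(
            vals, ["a", "b", "c", "a_rep"], ["P"] * 4, [f"l{i}" for i in range(229)],
            [None, None, None, "a"],
        )

    def test_identical_replicates_give_zero(self):
        assert genotyping_error_rate(self._with_replicate(False)) == 0.0

    def test_single_mismatch_over_229(self):
        assert genotyping_error_rate(self._with_replicate(True)) == pytest.approx(1 / 229)

    def test_no_replicates_is_error(self, tiny_matrix):
        with pytest.raises(ValueError):
            genotyping_error_rate(tiny_matrix)

    def test_recovers_simulated_flip_rate(self):
        cfg = SimulationConfig(seed=21, missing_rate=0.0)
        fr = simulate_hierarchical_frequencies(cfg)
        m = simulate_band_matrix(fr, cfg)
        rate = genotyping_error_rate(m)
        # 15 pairs x 229 loci comparisons; binomial 99.9% envelope
        n = 15 * 229
        se = np.sqrt(0.0078 * (1 - 0.0078) / n)
        assert abs(rate - 0.0078) < 4 * se


class TestSsaRegression:
    @pytest.mark.parametrize("hmc,ssa", [(0.488, 0.0), (1.813, 53.0), (2.113, 65.0)])
    def test_inverts_printed_regression(self, hmc, ssa):
        assert ssa_from_hmc(hmc) == pytest.approx(ssa, abs=1e-9)

    def test_below_intercept_clips_with_warning(self):
        with pytest.warns(UserWarning):
            assert ssa_from_hmc(0.2) == 0.0


class TestBiasCorrectedEstimator:
    def test_exceeds_sqrt_for_interior_counts(self):
        for absent, n in [(3, 15), (7, 15), (20, 100)]:
            s = estimate_null_allele_freq(absent, n, "sqrt")
            bc = estimate_null_allele_freq(absent, n, "bias_corrected")
            assert bc > s

    def test_zero_absent_gives_zero(self):
        assert estimate_null_allele_freq(0, 15, "bias_corrected") == 0.0

    def test_converges_to_sqrt(self):
        s = estimate_null_allele_freq(25_000, 100_000, "sqrt")
        bc = estimate_null_allele_freq(25_000, 100_000, "bias_corrected")
        assert bc == pytest.approx(s, abs=1e-5)

    def test_reduces_small_sample_bias(self):
        # mean of the corrected estimator is closer to the true q
        rng = np.random.default_rng(8)
        q = 0.4
        n = 15
        absent = rng.binomial(n, q * q, size=20_000)
        from aflpscape.estimators import null_freq_bias_corrected, null_freq_sqrt
        plain = null_freq_sqrt(absent, n).mean()
        corrected = null_freq_bias_corrected(absent, n).mean()
        assert abs(corrected - q) < abs(plain - q)
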