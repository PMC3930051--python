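"""Primitive estimators for dominant-marker data.

Band frequencies, null-allele (recessive) frequency estimation under
Hardy-Weinberg equilibrium, replicate-based genotyping error rate, and
the soil specific-surface-area regression used for the edaphic table.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import betaln

from .datatypes import BandMatrix, FrequencyTable

__all__ = [
    "band_frequencies",
    "estimate_null_allele_freq",
    "null_freq_sqrt",
    "null_freq_bayes",
    "genotyping_error_rate",
    "ssa_from_hmc",
]


def null_freq_sqrt(absent, n):
    """Square-root estimator of the null-allele frequency.

    Under HWE the band-absent phenotype has probability q**2, so
    ``q_hat = sqrt(absent / n)``.  Vectorized.
    """
    absent = np.asarray(absent, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(absent / n)
    return out


def null_freq_bias_corrected(absent, n):
    """Second-order bias-corrected square-root estimator.

    ``E[sqrt(x)] ~ sqrt(mu) - Var(x) / (8 mu^(3/2))`` for the absent
    fraction x, so adding the plug-in bias term
    ``sqrt(x) * (1 + x(1-x)/(8 n x^2))`` reduces the small-sample
    downward bias of the plain sqrt estimator.  Returns 0 when no
    absent phenotypes are observed.  Vectorized.
    """
    absent = np.asarray(absent, dtype=float)
    n = np.asarray(n, dtype=float)
    x = absent / n
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = 1.0 + (1.0 - x) / (8.0 * n * x)
        out = np.where(x > 0, np.sqrt(np.clip(x, 0, 1)) * corr, 0.0)
    return np.minimum(out, 1.0)


def null_freq_bayes(absent, n):
    """Posterior-mean null-allele frequency under a uniform prior on q.

    The likelihood of observing ``a`` band-absent individuals out of
    ``n`` is Binomial(n, q**2).  With a flat prior on q the posterior
    mean has the exact form (substituting u = q**2 in the normalizing
    integrals)::

        E[q | a, n] = B(a + 1, n - a + 1) / B(a + 1/2, n - a + 1)

    evaluated in log space for stability.  Strictly inside (0, 1) for
    any finite n, and converging to sqrt(a/n) as n grows.  Vectorized.
    """
    a = np.asarray(absent, dtype=float)
    n = np.asarray(n, dtype=float)
    return np.exp(betaln(a + 1.0, n - a + 1.0) - betaln(a + 0.5, n - a + 1.0))


def estimate_null_allele_freq(absent: int, n: int, method: str = "sqrt") -> float:
    """Estimate the null-allele frequency q from a band-absent count.

    Parameters
    ----------
    absent
        Number of individuals not showing the band.
    n
        Number of scored (non-missing) individuals; must be positive.
    method
        ``"sqrt"`` for the plug-in HWE estimator, ``"bayes_uniform"``
        for the posterior mean under a uniform prior (used by the
        F_ST outlier scan, where zero counts must not yield q = 0).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= absent <= n:
        raise ValueError("absent count outside [0, n]")
    if method == "sqrt":
        return float(null_freq_sqrt(absent, n))
    if method == "bayes_uniform":
        return float(null_freq_bayes(absent, n))
    if method == "bias_corrected":
        return float(null_freq_bias_corrected(absent, n))
    raise ValueError(f"unknown method {method!r}")


def band_frequencies(m: BandMatrix, method: str = "sqrt") -> FrequencyTable:
    """Per-population band frequencies and allele-frequency estimates.

    Band frequency is computed over non-missing entries only; cells
    where a population has no scored individuals at a locus are NaN and
    a warning is issued.  Replicate rows are excluded so each plant
    contributes once.
    """
    m = m.drop_replicates()
    pops = m.populations()
    idx = m.population_indices()
    P, L = len(pops), m.n_loci
    freq = np.empty((P, L))
    n_eff = np.empty((P, L), dtype=int)
    for i, pop in enumerate(pops):
        sub = m.values[idx[pop]]
        scored = ~np.isnan(sub)
        n_eff[i] = scored.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq[i] = np.nansum(sub, axis=0) / n_eff[i]
    if (n_eff == 0).any():
        warnings.warn("population x locus cells with no scored individuals; "
                      "frequencies undefined (NaN) there")
        freq[n_eff == 0] = np.nan
    absent = (1.0 - freq) * n_eff
    if method == "sqrt":
        q_hat = null_freq_sqrt(absent, n_eff)
    elif method == "bayes_uniform":
        q_hat = null_freq_bayes(absent, n_eff)
    elif method == "bias_corrected":
        q_hat = null_freq_bias_corrected(absent, n_eff)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FrequencyTable(pops, list(m.locus_names), freq, n_eff, q_hat, method)


def genotyping_error_rate(m: BandMatrix) -> float:
    """Mismatch error rate from replicated individuals.

    The rate is the total number of band-call mismatches between each
    replicate and its source individual, divided by the total number of
    jointly scored locus comparisons across all replicate pairs.
    """
    row = {ind: i for i, ind in enumerate(m.individual_ids)}
    mism = 0
    comps = 0
    for i, src in enumerate(m.replicate_of):
        if src is None:
            continue
        if src not in row:
            raise ValueError(f"replicate source {src!r} not in matrix")
        a = m.values[row[src]]
        b = m.values[i]
        shared = ~np.isnan(a) & ~np.isnan(b)
        comps += int(shared.sum())
        mism += int((a[shared] != b[shared]).sum())
    if comps == 0:
        raise ValueError("no replicate pairs present")
    return mism / comps


def ssa_from_hmc(hmc):
    """Soil specific surface area (m^2/g) from hygroscopic moisture.

    Inverts the calibration regression HMC (% w/w) = 0.025 * SSA + 0.488.
    Values of HMC below the intercept would give negative SSA; these are
    clipped to 0 with a warning.  Vectorized.
    """
    hmc = np.asarray(hmc, dtype=float)
    ssa = (hmc - 0.488) / 0.025
    if np.any(ssa < 0):
        warnings.warn("HMC below regression intercept 0.488; SSA clipped to 0")
        ssa = np.clip(ssa, 0.0, None)
    if ssa.ndim == 0:
        return float(ssa)
    return ssa
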