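"""Candidate-locus detection for dominant markers.

Three complementary scans:

* :func:`fdist_scan` — an F_ST outlier scan in the fdist tradition:
  per-locus F_ST is compared with a neutral (heterozygosity,
  F_ST) cloud simulated under a symmetric island approximation (a
  Balding-Nichols Beta model calibrated by bisection so the simulated
  mean F_ST matches the observed untrimmed mean), with conditional
  quantile envelopes, per-locus tail-mass p-values, and iterative
  removal of detected candidates.
* :func:`bayescan_scan` — a Bayesian decomposition of locus-population
  F_ST into population-specific (beta) and locus-specific (alpha)
  components; a locus is a candidate when the locus component is
  needed, summarized by posterior inclusion probabilities and
  q-values.
* :func:`sam_scan` — univariate logistic regressions of individual band
  presence on site-level predictors with joint Wald + G-test
  significance under a Bonferroni-corrected level.

All three operate on the polymorphic subset of the loci, estimate
dominant allele frequencies via the Bayesian uniform-prior estimator,
and are reproducible from a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, expit, logit

from .datatypes import BandMatrix
from .estimators import null_freq_bayes

__all__ = [
    "ScanConfig",
    "dominant_fst",
    "fdist_scan",
    "bayescan_scan",
    "sam_scan",
    "consensus_outliers",
    "locus_trait_correlation",
    "polymorphic_locus_mask",
]


@dataclass
class ScanConfig:
    """Tuning parameters shared by the scans (defaults are sensible
    desk-scale values; see docs/methods.md for rationale)."""

    n_sim: int = 50_000
    envelope_quantile: float = 0.99
    theta: float = 0.018
    iterate_removal: bool = True
    max_rounds: int = 5
    he_bins: int = 20
    min_bin_sims: int = 1000
    # MCMC (Bayesian locus-effect scan)
    chain_length: int = 10_000
    burn_in: int = 2_500
    thin: int = 1
    prior_inclusion_odds: float = 1.0 / 10.0
    q_threshold: float = 0.05
    # logistic association scan
    sam_alpha: float = 0.01
    polymorphism_level: float = 0.99

    def __post_init__(self) -> None:
        if not 0.5 < self.envelope_quantile < 1:
            raise ValueError("envelope quantile must be in (0.5, 1)")
        if self.theta <= 0:
            raise ValueError("theta must be positive")


# ---------------------------------------------------------------------------
# per-locus F_ST


def _counts(m: BandMatrix):
    """Per population x locus band counts: (present, scored)."""
    m = m.drop_replicates()
    pops = m.populations()
    idx = m.population_indices()
    L = m.n_loci
    present = np.zeros((len(pops), L))
    scored = np.zeros((len(pops), L))
    for i, p in enumerate(pops):
        sub = m.values[idx[p]]
        ok = ~np.isnan(sub)
        scored[i] = ok.sum(axis=0)
        present[i] = np.nansum(sub, axis=0)
    return present, scored, pops, list(m.locus_names)


def polymorphic_locus_mask(m: BandMatrix, level: float = 0.99) -> np.ndarray:
    """Loci polymorphic in the total sample at the given level.

    Uses the pooled square-root allele-frequency estimate; a locus is
    polymorphic when p_hat lies strictly inside (1 - level, level).
    """
    present, scored, *_ = _counts(m)
    tot_p = present.sum(axis=0)
    tot_n = scored.sum(axis=0)
    with np.errstate(invalid="ignore"):
        q = np.sqrt(np.clip(1.0 - tot_p / tot_n, 0, 1))
    p_hat = 1.0 - q
    return (p_hat > 1 - level) & (p_hat < level)


def _theta_he(p: np.ndarray, n_ind: np.ndarray):
    """ANOVA-form theta (F_ST) and pooled He per locus.

    ``p``: (P, L) presence-allele frequency estimates; ``n_ind``: (P, L)
    scored individual counts (allele counts are twice that).
    """
    mjs = 2.0 * n_ind
    msum = mjs.sum(axis=0)
    r = p.shape[0]
    pbar = (mjs * p).sum(axis=0) / msum
    msp = (mjs * (p - pbar) ** 2).sum(axis=0) / (r - 1)
    msg = (mjs * p * (1 - p)).sum(axis=0) / (msum - r)
    mc = (msum - (mjs ** 2).sum(axis=0) / msum) / (r - 1)
    denom = msp + (mc - 1.0) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom > 0, (msp - msg) / denom, 0.0)
    he = 2.0 * pbar * (1.0 - pbar)
    return theta, he


def dominant_fst(m: BandMatrix, level: float = 0.99) -> pd.DataFrame:
    """Locus-by-locus F_ST and heterozygosity for polymorphic loci.

    Allele frequencies per population come from the Bayesian
    uniform-prior null-frequency estimator (never exactly 0 or 1, as
    the neutral simulations require); theta is the variance-partition
    estimator from those frequencies and the per-cell sample sizes.
    Monomorphic loci are excluded; the untrimmed arithmetic mean across
    retained loci is stored in ``df.attrs["mean_fst"]``.
    """
    present, scored, pops, loci = _counts(m)
    poly = polymorphic_locus_mask(m, level)
    n_excluded = int((~poly).sum())
    present, scored = present[:, poly], scored[:, poly]
    loci = [l for l, keep in zip(loci, poly) if keep]
    absent = scored - present
    q = null_freq_bayes(absent, scored)
    p = 1.0 - q
    theta, he = _theta_he(p, scored)
    df = pd.DataFrame({"locus": loci, "fst": theta, "he": he})
    df.attrs["mean_fst"] = float(np.mean(theta))
    df.attrs["n_excluded_monomorphic"] = n_excluded
    df.attrs["populations"] = pops
    return df


# ---------------------------------------------------------------------------
# fdist-style outlier scan


def _simulate_neutral(F, n_loci, n_ind, rng):
    """Neutral (He, F_ST) pairs under the Beta island approximation.

    ``n_ind``: scored individuals per population.  Ancestral
    frequencies are Uniform(0.01, 0.99); loci monomorphic in the sample
    are resampled.  The estimation path (Bayesian q, ANOVA theta) is
    the same one applied to real data.
    """
    P = len(n_ind)
    he_out = np.empty(n_loci)
    fst_out = np.empty(n_loci)
    filled = 0
    while filled < n_loci:
        todo = max(int((n_loci - filled) * 1.4), 64)
        p_anc = rng.uniform(0.01, 0.99, todo)
        scale = (1.0 - F) / F
        pop_p = rng.beta(
            np.broadcast_to(p_anc * scale, (P, todo)),
            np.broadcast_to((1 - p_anc) * scale, (P, todo)),
        )
        qq = (1.0 - pop_p) ** 2
        nmat = np.broadcast_to(np.asarray(n_ind, dtype=float)[:, None], (P, todo))
        absent = rng.binomial(nmat.astype(int), qq)
        present = nmat - absent
        tot_pres = present.sum(axis=0)
        keep = (tot_pres > 0) & (absent.sum(axis=0) > 0)
        if not keep.any():
            continue
        absent, nmat = absent[:, keep], nmat[:, keep]
        qhat = null_freq_bayes(absent, nmat)
        theta, he = _theta_he(1.0 - qhat, nmat)
        take = min(theta.size, n_loci - filled)
        fst_out[filled:filled + take] = theta[:take]
        he_out[filled:filled + take] = he[:take]
        filled += take
    return he_out, fst_out


def _calibrate_F(target_mean, n_ind, seed, n_sim_calib=4000):
    """Bisection on the island-model F so the simulated untrimmed mean
    F_ST matches the observed one (common random numbers per
    evaluation keep the objective deterministic)."""

    def g(F):
        rng = np.random.default_rng(seed)
        _, fst = _simulate_neutral(F, n_sim_calib, n_ind, rng)
        return float(np.mean(fst)) - target_mean

    lo, hi = 1e-3, 0.8
    if g(lo) > 0:
        return lo
    if g(hi) < 0:
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return 0.5 * (lo + hi)


def _he_bins(he_sim, n_bins, min_sims):
    """Equal-width He bin edges, merging under-populated bins."""
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    counts, _ = np.histogram(he_sim, bins=edges)
    merged = [0.0]
    acc = 0
    for k in range(n_bins):
        acc += counts[k]
        if acc >= min_sims:
            merged.append(edges[k + 1])
            acc = 0
    if len(merged) < 2:
        merged.append(0.5)
    merged[-1] = 0.5
    return np.asarray(merged)


def fdist_scan(
    m: BandMatrix, cfg: ScanConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """F_ST outlier scan against a calibrated neutral envelope.

    Returns a per-locus frame with ``fst``, ``he``, upper-tail
    ``fdist_p`` (fraction of neutral simulated loci in the same He bin
    with F_ST at least as large), the informational lower-tail mass,
    the smoothed envelope quantile, and the candidate flag.  With
    ``iterate_removal`` the target mean is recomputed without detected
    candidates and the scan repeated until stable (at most
    ``max_rounds`` rounds).  ``df.attrs`` records the calibrated F per
    round.
    """
    cfg = cfg or ScanConfig()
    base = dominant_fst(m, cfg.polymorphism_level)
    _, scored, _, _ = _counts(m)
    n_ind = np.round(np.median(scored, axis=1)).astype(int)
    candidates: set[str] = set()
    rounds = []
    p_up = pd.Series(np.nan, index=base["locus"])
    p_lo = pd.Series(np.nan, index=base["locus"])
    env_at = pd.Series(np.nan, index=base["locus"])
    fst = base.set_index("locus")["fst"]
    he = base.set_index("locus")["he"]
    alpha = 1.0 - cfg.envelope_quantile
    for rnd in range(cfg.max_rounds):
        keep = [l for l in base["locus"] if l not in candidates]
        target = float(fst[keep].mean())
        F = _calibrate_F(target, n_ind, seed + 1000 * rnd)
        rng = np.random.default_rng(seed + 1000 * rnd + 1)
        he_sim, fst_sim = _simulate_neutral(F, cfg.n_sim, n_ind, rng)
        edges = _he_bins(he_sim, cfg.he_bins, min(cfg.min_bin_sims, cfg.n_sim // 4))
        bin_sim = np.clip(np.digitize(he_sim, edges) - 1, 0, len(edges) - 2)
        bin_obs = np.clip(np.digitize(he.values, edges) - 1, 0, len(edges) - 2)
        # conditional envelope quantile per bin, monotone-smoothed
        qs = np.array([
            np.quantile(fst_sim[bin_sim == b], cfg.envelope_quantile)
            if (bin_sim == b).any() else np.nan
            for b in range(len(edges) - 1)
        ])
        qs = np.fmax.accumulate(qs)  # non-decreasing in He
        new = set()
        for loc, b in zip(base["locus"], bin_obs):
            if loc in candidates:
                continue  # keep the p-value from the flagging round
            sims = fst_sim[bin_sim == b]
            up = float((sims >= fst[loc]).mean())
            lo = float((sims <= fst[loc]).mean())
            p_up[loc], p_lo[loc] = up, lo
            env_at[loc] = qs[b]
            if up <= alpha:
                new.add(loc)
        rounds.append({"round": rnd, "target_mean_fst": target, "F": F,
                       "new_candidates": sorted(new)})
        if not new or not cfg.iterate_removal:
            candidates |= new
            break
        candidates |= new
    out = base.copy()
    out["fdist_p"] = p_up.values
    out["fdist_p_lower"] = p_lo.values
    out["envelope_fst"] = env_at.values
    out["fdist_candidate"] = [l in candidates for l in out["locus"]]
    out.attrs.update(base.attrs)
    out.attrs["rounds"] = rounds
    out.attrs["seed"] = seed
    return out


# ---------------------------------------------------------------------------
# Bayesian locus-effect decomposition


def _beta_logpdf_terms(x, a, b):
    """Log density of Beta(a, b) at p = expit(x), in logit space
    (Jacobian included): a*log p + b*log(1-p) - B(a, b)."""
    logp = -np.logaddexp(0.0, -x)
    log1mp = -np.logaddexp(0.0, x)
    return a * logp + b * log1mp - betaln(a, b)


def _dominant_loglik(x, absent, n):
    """Binomial log-likelihood of absence counts given logit presence
    frequency: absent ~ Bin(n, (1-p)^2)."""
    log1mp = -np.logaddexp(0.0, x)      # log q
    qq = np.exp(2.0 * log1mp)
    log_band = np.log1p(-np.minimum(qq, 1.0 - 1e-12))
    return 2.0 * absent * log1mp + (n - absent) * log_band


def bayescan_scan(
    m: BandMatrix, cfg: ScanConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Bayesian decomposition of locus-population F_ST.

    Model: ``logit(F_ij) = delta_i * alpha_i + beta_j`` with locus
    effects alpha ~ N(0,1) toggled by inclusion indicators delta
    (prior odds ``cfg.prior_inclusion_odds``), population effects
    beta ~ N(-1,1), latent population frequencies
    ``p_ij ~ Beta(theta_ij p_i, theta_ij (1-p_i))`` with
    ``theta_ij = (1-F_ij)/F_ij`` around uniform-prior ancestral
    frequencies, and the dominant-marker absence likelihood.  Updated
    by random-walk Metropolis within Gibbs with pilot adaptation of
    the proposal scales during burn-in.

    Returns per-locus posterior inclusion probability (PIP), the
    posterior mean locus effect, and q-values (expected false-positive
    fraction at each PIP cutoff); candidates satisfy
    ``q <= cfg.q_threshold``.
    """
    cfg = cfg or ScanConfig()
    rng = np.random.default_rng(seed)
    present, scored, pops, loci = _counts(m)
    poly = polymorphic_locus_mask(m, cfg.polymorphism_level)
    present, scored = present[:, poly].T, scored[:, poly].T  # (L, J)
    loci = [l for l, k in zip(loci, poly) if k]
    absent = scored - present
    L, J = present.shape
    pi_incl = cfg.prior_inclusion_odds / (1.0 + cfg.prior_inclusion_odds)

    # initial values from moment estimates
    q0 = null_freq_bayes(absent, np.maximum(scored, 1))
    p0 = np.clip(1.0 - q0, 1e-3, 1 - 1e-3)
    x = logit(p0)                                   # (L, J) latent freqs
    panc = np.clip(p0.mean(axis=1), 1e-3, 1 - 1e-3)
    y = logit(panc)                                 # (L,) ancestral
    alpha = np.zeros(L)
    delta = np.zeros(L, dtype=bool)
    beta = np.full(J, -1.0)
    s_x, s_y, s_a, s_b = 0.5, 0.3, 0.5, 0.15

    def beta_terms(alpha_eff, beta_v, y_v, x_v):
        f = expit(alpha_eff[:, None] + beta_v[None, :])
        f = np.clip(f, 1e-6, 1 - 1e-6)
        th = (1.0 - f) / f
        pa = expit(y_v)
        a = th * pa[:, None]
        b = th * (1.0 - pa)[:, None]
        return _beta_logpdf_terms(x_v, a, b)

    def data_terms(x_v):
        return _dominant_loglik(x_v, absent, scored)

    bt = beta_terms(np.where(delta, alpha, 0.0), beta, y, x)
    dt = data_terms(x)

    keep_iters = cfg.chain_length - cfg.burn_in
    pip_acc = np.zeros(L)
    alpha_acc = np.zeros(L)
    alpha_cnt = np.zeros(L)
    beta_draws = np.empty((keep_iters, J))
    n_kept = 0
    for it in range(cfg.chain_length):
        a_eff = np.where(delta, alpha, 0.0)
        # 1. latent frequencies
        xp = x + rng.normal(0.0, s_x, x.shape)
        btp = beta_terms(a_eff, beta, y, xp)
        dtp = data_terms(xp)
        acc = np.log(rng.random(x.shape)) < (btp + dtp - bt - dt)
        x = np.where(acc, xp, x)
        bt = np.where(acc, btp, bt)
        dt = np.where(acc, dtp, dt)
        acc_x = float(acc.mean())
        # 2. ancestral frequencies (uniform prior on p_anc)
        yp = y + rng.normal(0.0, s_y, L)
        btp = beta_terms(a_eff, beta, yp, x)
        cur = bt.sum(axis=1) + (-np.logaddexp(0, -y) - np.logaddexp(0, y))
        prop = btp.sum(axis=1) + (-np.logaddexp(0, -yp) - np.logaddexp(0, yp))
        accv = np.log(rng.random(L)) < (prop - cur)
        y = np.where(accv, yp, y)
        bt = np.where(accv[:, None], btp, bt)
        acc_y = float(accv.mean())
        # 3. locus effects: RW where included, prior refresh where not
        acc_a = 0.3
        inc = np.flatnonzero(delta)
        if inc.size:
            ap = alpha[inc] + rng.normal(0.0, s_a, inc.size)
            btp = beta_terms(ap, beta, y[inc], x[inc])
            lr = (btp.sum(axis=1) - bt[inc].sum(axis=1)
                  - 0.5 * (ap ** 2 - alpha[inc] ** 2))
            accv = np.log(rng.random(inc.size)) < lr
            alpha[inc[accv]] = ap[accv]
            bt[inc[accv]] = btp[accv]
            acc_a = float(accv.mean())
        alpha[~delta] = rng.normal(0.0, 1.0, int((~delta).sum()))
        # 4. inclusion toggles
        if pi_incl > 0:
            a_eff_p = np.where(delta, 0.0, alpha)  # flipped state
            btp = beta_terms(a_eff_p, beta, y, x)
            prior_lr = np.where(
                delta,
                np.log1p(-pi_incl) - np.log(pi_incl),
                np.log(pi_incl) - np.log1p(-pi_incl),
            )
            lr = btp.sum(axis=1) - bt.sum(axis=1) + prior_lr
            accv = np.log(rng.random(L)) < lr
            delta = np.where(accv, ~delta, delta)
            bt = np.where(accv[:, None], btp, bt)
        # 5. population effects (sequential, one matrix column at a time)
        a_eff = np.where(delta, alpha, 0.0)
        pa = expit(y)
        for j in range(J):
            bprop = beta[j] + rng.normal(0.0, s_b)
            f = np.clip(expit(a_eff + bprop), 1e-6, 1 - 1e-6)
            th = (1.0 - f) / f
            btp_j = _beta_logpdf_terms(x[:, j], th * pa, th * (1.0 - pa))
            lr = (btp_j.sum() - bt[:, j].sum()
                  - 0.5 * ((bprop + 1.0) ** 2 - (beta[j] + 1.0) ** 2))
            if np.log(rng.random()) < lr:
                beta[j] = bprop
                bt[:, j] = btp_j
        # pilot adaptation during burn-in
        if it < cfg.burn_in and (it + 1) % 50 == 0:
            s_x *= np.exp(0.5 * (acc_x - 0.3))
            s_y *= np.exp(0.5 * (acc_y - 0.3))
            s_a *= np.exp(0.5 * (acc_a - 0.3))
        if it >= cfg.burn_in:
            pip_acc += delta
            alpha_acc += np.where(delta, alpha, 0.0)
            alpha_cnt += delta
            beta_draws[n_kept] = beta
            n_kept += 1

    pip = pip_acc / keep_iters
    with np.errstate(invalid="ignore"):
        alpha_mean = np.where(alpha_cnt > 0, alpha_acc / np.maximum(alpha_cnt, 1), 0.0)
    rhat = _split_rhat(beta_draws[:n_kept])
    if np.nanmax(rhat) > 1.2:
        warnings.warn(
            f"population-effect chains may not have mixed (max split-Rhat "
            f"{np.nanmax(rhat):.2f} > 1.2); consider longer chains"
        )
    # q-values: expected false-positive fraction at each PIP cutoff
    qvals = np.empty(L)
    for i in range(L):
        sel = pip >= pip[i]
        qvals[i] = float((1.0 - pip[sel]).mean())
    out = pd.DataFrame({
        "locus": loci,
        "pip": pip,
        "alpha_mean": alpha_mean,
        "qvalue": qvals,
        "bayescan_candidate": qvals <= cfg.q_threshold,
    })
    out.attrs["max_split_rhat"] = float(np.nanmax(rhat))
    out.attrs["seed"] = seed
    return out


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-R-hat per column from a single chain split in half."""
    n = (draws.shape[0] // 2) * 2
    if n < 4:
        return np.full(draws.shape[1], np.nan)
    halves = draws[:n].reshape(2, n // 2, -1)
    m = halves.mean(axis=1)
    v = halves.var(axis=1, ddof=1)
    W = v.mean(axis=0)
    B = (n // 2) * m.var(axis=0, ddof=1)
    var_hat = (n // 2 - 1) / (n // 2) * W + B / (n // 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(var_hat / W)


# ---------------------------------------------------------------------------
# logistic environmental-association scan


def _logistic_irls(y, mask, xcol, tol=1e-8, max_iter=100):
    """Vectorized 2-parameter logistic IRLS across loci.

    ``y``: (n, L) band presence with NaN for missing; ``mask``: scored
    entries; ``xcol``: (n,) predictor.  Returns slope, slope SE, model
    and null log-likelihoods, and a convergence/separation flag.
    """
    n, L = y.shape
    yz = np.where(mask, np.nan_to_num(y), 0.0)
    X1 = np.ones(n)
    b0 = np.zeros(L)
    b1 = np.zeros(L)
    unstable = np.zeros(L, dtype=bool)
    for _ in range(max_iter):
        eta = b0[None, :] + np.outer(xcol, b1)
        mu = expit(eta)
        w = np.where(mask, mu * (1 - mu), 0.0)
        z = eta + np.where(mask, (yz - mu), 0.0) / np.maximum(w, 1e-12)
        # weighted 2x2 normal equations per locus
        s00 = w.sum(axis=0)
        s01 = (w * xcol[:, None]).sum(axis=0)
        s11 = (w * (xcol ** 2)[:, None]).sum(axis=0)
        t0 = (w * z).sum(axis=0)
        t1 = (w * z * xcol[:, None]).sum(axis=0)
        det = s00 * s11 - s01 ** 2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        nb0 = (s11 * t0 - s01 * t1) / det
        nb1 = (s00 * t1 - s01 * t0) / det
        d = np.abs(np.vstack([nb0 - b0, nb1 - b1]))
        step = np.max(np.where(np.isnan(d), 0.0, d), axis=0)
        b0 = np.where(np.isnan(nb0), b0, nb0)
        b1 = np.where(np.isnan(nb1), b1, nb1)
        diverged = np.abs(b1) > 15
        unstable |= diverged | np.isnan(nb0)
        stable = ~unstable
        if not stable.any() or np.all(step[stable] < tol):
            break
    eta = b0[None, :] + np.outer(xcol, b1)
    ll = np.where(mask, yz * eta - np.logaddexp(0.0, eta), 0.0).sum(axis=0)
    # intercept-only null: closed form at the observed band fraction
    ybar = yz.sum(axis=0) / np.maximum(mask.sum(axis=0), 1)
    ybar = np.clip(ybar, 1e-12, 1 - 1e-12)
    ll0 = (yz.sum(axis=0) * np.log(ybar)
           + (mask.sum(axis=0) - yz.sum(axis=0)) * np.log1p(-ybar))
    # slope SE from the weighted information matrix at the optimum
    mu = expit(eta)
    w = np.where(mask, mu * (1 - mu), 0.0)
    s00 = w.sum(axis=0)
    s01 = (w * xcol[:, None]).sum(axis=0)
    s11 = (w * (xcol ** 2)[:, None]).sum(axis=0)
    det = s00 * s11 - s01 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(s00 / det)
    unstable |= ~np.isfinite(se1)
    return b1, se1, ll, ll0, unstable


def sam_scan(
    m: BandMatrix,
    predictors: pd.DataFrame,
    alpha: float = 0.01,
    level: float = 0.99,
) -> pd.DataFrame:
    """Logistic association of band presence with site-level predictors.

    ``predictors`` has one row per population (indexed or with a
    ``population`` column) and one column per predictor (typically the
    first two environmental PCA axes); values are broadcast to
    individuals.  For each polymorphic locus x predictor the Wald test
    (slope / SE) and the G-test (2 * likelihood-ratio, 1 df) are
    computed; an association is significant only when both reject at
    the Bonferroni level ``alpha / m`` with ``m = #loci x #predictors``.
    Loci with complete separation are flagged unstable and excluded
    from the significant set.
    """
    base = m.drop_replicates()
    poly = polymorphic_locus_mask(base, level)
    sub = base.subset_loci(np.flatnonzero(poly))
    if "population" in predictors.columns:
        predictors = predictors.set_index("population")
    missing = [p for p in sub.populations() if p not in predictors.index]
    if missing:
        raise ValueError(f"populations missing from predictors: {missing}")
    pred_names = list(predictors.columns)
    m_models = len(sub.locus_names) * len(pred_names)
    threshold = alpha / m_models
    y = sub.values
    mask = ~np.isnan(y)
    rows = []
    for name in pred_names:
        xcol = np.array([predictors.loc[p, name] for p in sub.population_ids], dtype=float)
        if np.std(xcol) == 0:
            raise ValueError(f"predictor {name!r} constant across individuals")
        b1, se1, ll, ll0, unstable = _logistic_irls(y, mask, xcol)
        g = np.clip(2.0 * (ll - ll0), 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            wald_p = 2.0 * stats.norm.sf(np.abs(b1 / se1))
        g_p = stats.chi2.sf(g, df=1)
        sig = (wald_p < threshold) & (g_p < threshold) & ~unstable
        for i, loc in enumerate(sub.locus_names):
            rows.append({
                "locus": loc, "predictor": name, "slope": b1[i],
                "wald_p": wald_p[i], "g_p": g_p[i], "g_stat": g[i],
                "unstable": bool(unstable[i]), "significant": bool(sig[i]),
            })
    out = pd.DataFrame(rows)
    out.attrs["n_models"] = m_models
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# consensus and trait correlation


def consensus_outliers(records: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-method candidate flags into a consensus table.

    ``records`` maps method name to that scan's output frame (fdist /
    bayescan frames with their ``*_candidate`` column; the logistic
    scan's frame with per-predictor ``significant`` rows).  The result
    has one row per locus flagged by any method, with per-method
    flags, the count of detecting methods, and per-method detection
    percentages (of polymorphic loci) in ``attrs``.
    """
    flags: dict[str, set] = {}
    universe: set = set()
    for method, df in records.items():
        if "significant" in df.columns and "predictor" in df.columns:
            sel = set(df.loc[df["significant"], "locus"])
            universe |= set(df["locus"])
        else:
            col = [c for c in df.columns if c.endswith("_candidate")]
            sel = set(df.loc[df[col[0]], "locus"]) if col else set()
            universe |= set(df["locus"])
        flags[method] = sel
    fst_lookup = {}
    for df in records.values():
        if "fst" in df.columns:
            fst_lookup.update(dict(zip(df["locus"], df["fst"])))
    all_hits = sorted(set().union(*flags.values()))
    rows = []
    for loc in all_hits:
        row = {"locus": loc}
        for method in records:
            row[method] = loc in flags[method]
        row["n_methods"] = sum(row[m] for m in records)
        row["fst"] = fst_lookup.get(loc, np.nan)
        rows.append(row)
    out = pd.DataFrame(rows, columns=["locus", *records, "n_methods", "fst"])
    if len(out):
        out = out.sort_values(["n_methods", "fst"], ascending=False).reset_index(drop=True)
    n_poly = max(len(universe), 1)
    out.attrs["percent_detected"] = {
        m: 100.0 * len(s) / n_poly for m, s in flags.items()
    }
    out.attrs["percent_detected_overall"] = 100.0 * len(set().union(*flags.values())) / n_poly
    return out


def _prune_correlated_traits(df: pd.DataFrame, traits: list[str], r_prune: float):
    """Greedily drop traits until no pair correlates above r_prune; the
    trait with the larger mean absolute correlation to the others goes
    first."""
    traits = list(traits)
    while len(traits) > 1:
        corr = df[traits].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= r_prune:
            break
        mean_i = corr[i].sum() / (len(traits) - 1)
        mean_j = corr[j].sum() / (len(traits) - 1)
        traits.pop(i if mean_i >= mean_j else j)
    return traits


def locus_trait_correlation(
    freqs,
    candidate_loci: list[str],
    phenotypes: dict[str, pd.DataFrame],
    r_prune: float = 0.7,
    method: str = "holm",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate candidate-locus band frequencies with trait means.

    Within each experiment, traits are greedily pruned until no pair
    exceeds ``|r| > r_prune``; Pearson r and its two-sided t-test
    p-value are computed per (locus, retained trait); the correction
    (``holm`` default, ``bonferroni`` by flag) is applied across all
    tested pairs from all experiments.
    """
    from statsmodels.stats.multitest import multipletests

    loc_idx = {l: k for k, l in enumerate(freqs.loci)}
    missing = [l for l in candidate_loci if l not in loc_idx]
    if missing:
        raise ValueError(f"unknown candidate loci: {missing}")
    rows = []
    for exp, table in phenotypes.items():
        table = table.set_index("population") if "population" in table.columns else table
        pops = [p for p in freqs.populations if p in table.index]
        if len(pops) < 4:
            raise ValueError(f"experiment {exp!r} shares <4 populations with the frequencies")
        traits = [
            c for c in table.columns
            if c != "experiment" and np.issubdtype(table[c].dtype, np.number)
        ]
        keep = []
        for t in traits:
            if table.loc[pops, t].std() == 0:
                warnings.warn(f"trait {t!r} has zero variance; dropped")
            else:
                keep.append(t)
        retained = _prune_correlated_traits(table.loc[pops], keep, r_prune)
        for loc in candidate_loci:
            f = freqs.freq[[freqs.populations.index(p) for p in pops], loc_idx[loc]]
            for t in retained:
                vals = table.loc[pops, t].to_numpy(dtype=float)
                r, p = stats.pearsonr(f, vals)
                rows.append({"experiment": exp, "locus": loc, "trait": t,
                             "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        rej, adj, *_ = multipletests(out["p"], alpha=alpha, method=method)
        out["p_adjusted"] = adj
        out["significant"] = rej
        out = out.sort_values("p_adjusted").reset_index(drop=True)
    return out
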