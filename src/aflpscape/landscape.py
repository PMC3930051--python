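"""Distance-matrix construction and the cluster-grouped mixed model.

The isolation-by-distance / isolation-by-adaptation analysis regresses
linearized genetic distances ``Phi/(1 - Phi)`` on ln-transformed
geographic distances and environmental (PCA-space Euclidean) distances,
while absorbing population substructure through a random intercept over
pair categories (within-cluster, between-cluster, admixed-involved).
Fixed effects are tested with a parametric-bootstrap likelihood-ratio
test: response data are simulated from the fitted null model and both
nested models are refitted to each simulated response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "PcaResult",
    "DistanceSet",
    "LmmFit",
    "BootstrapTest",
    "environment_pca",
    "haversine_km",
    "build_distance_set",
    "fit_distance_lmm",
    "parametric_bootstrap_lrt",
    "unfold",
]

#: floor (km) applied before the log transform of geographic distance,
#: so nearly co-located sites do not produce ln(0)
GEO_FLOOR_KM = 0.1
#: Phi_ST is clamped to [0, PHI_CLAMP] before linearization; negative
#: estimates are sampling noise, values at 1 would diverge
PHI_CLAMP = 0.999


@dataclass
class PcaResult:
    scores: np.ndarray            # (sites, axes)
    loadings: np.ndarray          # (variables, axes)
    variance_explained: np.ndarray
    variables: list[str]
    sites: list[str]


def environment_pca(site_table: pd.DataFrame, variables: list[str]) -> PcaResult:
    """PCA of site variables on the correlation matrix.

    Variables are z-scored (sample sd), the correlation matrix is
    eigendecomposed, and scores are the standardized data projected on
    the eigenvectors.  Sign convention: each axis is oriented so that
    its largest-magnitude loading is positive.  Missing values are
    refused, constant variables are named in the error.
    """
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    X = site_table[variables].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 sites")
    if np.isnan(X).any():
        raise ValueError("missing values in site table; imputation refused")
    sd = X.std(axis=0, ddof=1)
    const = [v for v, s in zip(variables, sd) if s == 0]
    if const:
        raise ValueError(f"constant variable(s): {', '.join(const)}")
    Z = (X - X.mean(axis=0)) / sd
    R = (Z.T @ Z) / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    for k in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, k])), k] < 0:
            vecs[:, k] = -vecs[:, k]
    return PcaResult(
        Z @ vecs, vecs, vals / vals.sum(), list(variables),
        list(site_table["population"]) if "population" in site_table else
        [str(i) for i in range(X.shape[0])],
    )


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in kilometres."""
    r = 6371.0088
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * r * np.arcsin(np.sqrt(a)))


@dataclass
class DistanceSet:
    populations: list[str]
    genetic: np.ndarray        # linearized Phi/(1-Phi)
    geographic: np.ndarray     # ln km (floored)
    environmental: np.ndarray  # Euclidean over first k PCA axes
    category: np.ndarray       # object array of pair-category codes


def build_distance_set(
    phist: np.ndarray,
    populations: list[str],
    site_table: pd.DataFrame,
    pca: PcaResult,
    cluster_labels: dict[str, str],
    admixed: set[str] | list[str] = (),
    k_axes: int = 4,
    fine_categories: bool = False,
) -> DistanceSet:
    """Assemble the genetic / geographic / environmental / category set.

    Genetic: ``Phi/(1-Phi)`` with Phi clamped to [0, 0.999].  Geographic:
    ``ln(max(haversine_km, 0.1))``.  Environmental: Euclidean distance
    over the first ``k_axes`` PCA scores.  Category: ``within`` (same
    cluster), ``between`` (different clusters), ``admixed`` (either
    population admixed) — the pooled 3-level default; with
    ``fine_categories`` the within and admixed codes are split per
    cluster (e.g. ``within:C1``, ``admixed:C2``), a sensitivity option
    since three levels is already few for a variance estimate.
    """
    P = len(populations)
    admixed = set(admixed)
    for p in populations:
        if p not in cluster_labels:
            raise ValueError(f"population {p!r} missing from cluster labels")
    site = site_table.set_index("population")
    missing = [p for p in populations if p not in site.index]
    if missing:
        raise ValueError(f"populations missing from site table: {missing}")
    k = min(k_axes, pca.scores.shape[1])
    score_row = {s: pca.scores[i, :k] for i, s in enumerate(pca.sites)}
    gen = np.zeros((P, P))
    geo = np.zeros((P, P))
    env = np.zeros((P, P))
    cat = np.empty((P, P), dtype=object)
    for i in range(P):
        cat[i, i] = None
        for j in range(i + 1, P):
            a, b = populations[i], populations[j]
            phi = min(max(phist[i, j], 0.0), PHI_CLAMP)
            gen[i, j] = gen[j, i] = phi / (1.0 - phi)
            km = haversine_km(
                site.loc[a, "latitude"], site.loc[a, "longitude"],
                site.loc[b, "latitude"], site.loc[b, "longitude"],
            )
            geo[i, j] = geo[j, i] = np.log(max(km, GEO_FLOOR_KM))
            env[i, j] = env[j, i] = float(
                np.linalg.norm(score_row[a] - score_row[b])
            )
            if a in admixed or b in admixed:
                c = "admixed"
                if fine_categories:
                    other = b if a in admixed else a
                    c = f"admixed:{cluster_labels[other]}"
            elif cluster_labels[a] == cluster_labels[b]:
                c = "within"
                if fine_categories:
                    c = f"within:{cluster_labels[a]}"
            else:
                c = "between"
            cat[i, j] = cat[j, i] = c
    return DistanceSet(list(populations), gen, geo, env, cat)


def unfold(matrix: np.ndarray) -> np.ndarray:
    """Lower triangle (i > j) of a square matrix as a vector."""
    idx = np.tril_indices(matrix.shape[0], k=-1)
    return np.asarray(matrix[idx])


# ---------------------------------------------------------------------------
# linear mixed model on unfolded pairwise distances


@dataclass
class LmmFit:
    fixed_names: list[str]
    beta: np.ndarray
    beta_se: np.ndarray
    sigma_u2: float
    sigma2: float
    loglik: float
    fitted: np.ndarray
    r2: float
    category_levels: list[str]
    random_effects: np.ndarray


def _design(ds: DistanceSet, fixed):
    y = unfold(ds.genetic)
    cols = [np.ones_like(y)]
    names = ["intercept"]
    if "geo" in fixed:
        cols.append(unfold(ds.geographic))
        names.append("geo")
    if "env" in fixed:
        cols.append(unfold(ds.environmental))
        names.append("env")
    X = np.column_stack(cols)
    cats = unfold_categories(ds)
    levels = sorted(set(cats))
    Z = np.zeros((len(y), len(levels)))
    for k, lv in enumerate(levels):
        Z[np.asarray(cats) == lv, k] = 1.0
    return y, X, names, Z, levels


def unfold_categories(ds: DistanceSet) -> list[str]:
    idx = np.tril_indices(len(ds.populations), k=-1)
    return [ds.category[i, j] for i, j in zip(*idx)]


def _profiled_ml(y, X, Z):
    """Maximize the ML likelihood profiling out beta and sigma2.

    The random-intercept covariance is ``sigma_u2 * Z Z'``; with
    ``lam = sigma_u2 / sigma2`` the marginal covariance is
    ``sigma2 * (I + lam Z Z')``.  One eigendecomposition of ``Z Z'``
    turns every likelihood evaluation into O(n) diagonal weighting.
    """
    n = len(y)
    ZZt = Z @ Z.T
    d, Q = np.linalg.eigh(ZZt)
    d = np.clip(d, 0.0, None)
    yt = Q.T @ y
    Xt = Q.T @ X

    def neg_profile_loglik(t):
        lam = np.exp(t)
        w = 1.0 + lam * d
        sw = 1.0 / np.sqrt(w)
        beta, *_ = np.linalg.lstsq(Xt * sw[:, None], yt * sw, rcond=None)
        r = yt - Xt @ beta
        rss = float(np.sum(r * r / w))
        sigma2 = rss / n
        ll = -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * np.sum(np.log(w)) - 0.5 * n
        return -ll

    res = minimize_scalar(
        neg_profile_loglik, bounds=(-30.0, 30.0), method="bounded",
        options={"xatol": 1e-10},
    )
    # compare against the sigma_u2 = 0 boundary explicitly
    ll_opt = -res.fun
    ll_zero = -neg_profile_loglik(-60.0)  # effectively sigma_u2 = 0
    if ll_zero >= ll_opt:
        t_hat, ll = -np.inf, ll_zero
        lam = 0.0
    else:
        t_hat, ll = res.x, ll_opt
        lam = float(np.exp(t_hat))
    w = 1.0 + lam * d
    sw = 1.0 / np.sqrt(w)
    beta, *_ = np.linalg.lstsq(Xt * sw[:, None], yt * sw, rcond=None)
    r = yt - Xt @ beta
    sigma2 = float(np.sum(r * r / w) / n)
    XtVX = (Xt / w[:, None]).T @ Xt
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    return beta, np.sqrt(np.diag(cov_beta)), lam, sigma2, float(ll)


def fit_distance_lmm(
    ds: DistanceSet, fixed=("geo", "env"), category_mode: str = "random"
) -> LmmFit:
    """ML fit of the pair-category random-intercept model.

    ``y = X beta + u_category + eps`` on the unfolded pairwise vector,
    with ``u ~ N(0, sigma_u2)`` i.i.d. per category level.  ML (not
    REML) so that likelihood-ratio tests across fixed-effect structures
    are valid.  ``fitted`` includes the predicted (BLUP) random
    effects; ``r2`` is the squared correlation of observed and fitted.

    ``category_mode="fixed"`` instead enters the categories as fixed
    dummy contrasts (no variance component) — a sensitivity mode,
    since a variance estimated from three category levels is weakly
    identified.
    """
    y, X, names, Z, levels = _design(ds, fixed)
    counts = Z.sum(axis=0)
    if (counts >= 2).sum() < 2:
        raise ValueError("need >=2 category levels with >=2 pairs each")
    if category_mode == "fixed":
        X = np.column_stack([X, Z[:, 1:]])  # first level absorbed by intercept
        names = names + [f"cat[{lv}]" for lv in levels[1:]]
        Z = np.zeros((len(y), 0))
    elif category_mode != "random":
        raise ValueError(f"unknown category_mode {category_mode!r}")
    beta, se, lam, sigma2, ll = _profiled_ml(y, X, Z)
    resid = y - X @ beta
    # BLUP: u = lam Z' (I + lam Z Z')^{-1} r
    V = np.eye(len(y)) + lam * (Z @ Z.T)
    u = lam * (Z.T @ np.linalg.solve(V, resid))
    fitted = X @ beta + Z @ u
    if np.std(fitted) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    else:
        r2 = 0.0
    return LmmFit(
        names, beta, se, lam * sigma2, sigma2, ll, fitted, r2, levels, u
    )


@dataclass
class BootstrapTest:
    lr_observed: float
    lr_simulated: np.ndarray
    p_value: float
    seed: int
    n_redraws: int = 0


def parametric_bootstrap_lrt(
    ds: DistanceSet,
    full_fixed=("geo", "env"),
    reduced_fixed=(),
    B: int = 1000,
    seed: int = 0,
) -> BootstrapTest:
    """Parametric-bootstrap LR test of nested fixed-effect structures.

    Fits the reduced model by ML, simulates ``B`` responses from it
    (fresh random intercepts and residuals at the estimated variances),
    refits both models to each simulated response, and compares the
    observed ``2 * (l_full - l_reduced)`` with the simulated
    distribution: ``p = (1 + #{sim >= obs}) / (B + 1)``.
    """
    if not set(reduced_fixed) <= set(full_fixed):
        raise ValueError("reduced model must be nested in the full model")
    rng = np.random.default_rng(seed)
    y, Xf, _, Z, levels = _design(ds, full_fixed)
    _, Xr, _, _, _ = _design(ds, reduced_fixed)
    br, _, lam_r, s2_r, ll_r = _profiled_ml(y, Xr, Z)
    bf, _, lam_f, s2_f, ll_f = _profiled_ml(y, Xf, Z)
    lr_obs = max(0.0, 2.0 * (ll_f - ll_r))
    su = np.sqrt(lam_r * s2_r)
    se = np.sqrt(s2_r)
    mu = Xr @ br
    sims = np.empty(B)
    for b in range(B):
        u = rng.normal(0.0, su, Z.shape[1])
        ystar = mu + Z @ u + rng.normal(0.0, se, len(y))
        *_, llr = _profiled_ml(ystar, Xr, Z)
        *_, llf = _profiled_ml(ystar, Xf, Z)
        sims[b] = max(0.0, 2.0 * (llf - llr))
    p = (1 + int((sims >= lr_obs).sum())) / (B + 1)
    return BootstrapTest(lr_obs, sims, p, seed)
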