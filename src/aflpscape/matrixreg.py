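"""Permutation-based regression and correlation of distance matrices.

Multiple regression on distance matrices (MRM) unfolds the lower
triangles, fits OLS, and assesses significance by matrix-preserving
permutations of the dependent matrix (its rows and columns permuted
together).  The partial Mantel test correlates the residuals of two
matrices after regressing each on the control matrices, permuting the
residualized first matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import unfold

__all__ = [
    "MrmResult",
    "MantelResult",
    "mrm",
    "forward_stepwise",
    "partial_mantel",
    "cluster_distance_matrix",
]


@dataclass
class MrmResult:
    predictor_names: list[str]
    coefficients: np.ndarray      # intercept first
    r2: float
    p_r2: float
    p_coefficients: np.ndarray    # aligned with coefficients (intercept NaN)
    n_permutations: int
    seed: int


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    controls: list[str]
    seed: int


def _check_square(mats):
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("matrices must be square and aligned")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("matrices must be symmetric")
    return n


def _permute_matrix(m: np.ndarray, perm: np.ndarray) -> np.ndarray:
    return m[np.ix_(perm, perm)]


def mrm(
    y: np.ndarray,
    X: list[np.ndarray],
    names: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> MrmResult:
    """Multiple regression of one distance matrix on several others."""
    n = _check_square([y] + list(X))
    names = names or [f"x{i + 1}" for i in range(len(X))]
    yv = unfold(y)
    D = np.column_stack([np.ones_like(yv)] + [unfold(m) for m in X])
    if np.linalg.cond(D) > 1e10:
        raise ValueError("collinear predictor matrices (condition number > 1e10)")
    pinv = np.linalg.pinv(D)
    coef = pinv @ yv
    fitted = D @ coef
    sst = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - float(np.sum((yv - fitted) ** 2)) / sst if sst > 0 else 0.0
    rng = np.random.default_rng(seed)
    count_r2 = 0
    count_coef = np.zeros(len(coef))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ypv = unfold(_permute_matrix(y, perm))
        c = pinv @ ypv
        f = D @ c
        sstp = float(np.sum((ypv - ypv.mean()) ** 2))
        r2p = 1.0 - float(np.sum((ypv - f) ** 2)) / sstp if sstp > 0 else 0.0
        if r2p >= r2:
            count_r2 += 1
        count_coef += np.abs(c) >= np.abs(coef)
    p_r2 = (1 + count_r2) / (n_perm + 1)
    p_coef = (1 + count_coef) / (n_perm + 1)
    p_coef[0] = np.nan  # intercept not tested
    return MrmResult(names, coef, r2, p_r2, p_coef, n_perm, seed)


def forward_stepwise(
    y: np.ndarray,
    candidates: dict[str, np.ndarray],
    p_enter: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
):
    """Forward selection of predictor matrices with a P-to-enter rule.

    At each step the candidate giving the largest increase in R² is
    tested by permutation (of the dependent matrix, refitting the
    current-plus-candidate model); it enters if its partial p-value is
    at most ``p_enter``.  Returns ``(selection order with per-step
    statistics, final MrmResult or None)``.
    """
    n = _check_square([y] + list(candidates.values()))
    rng = np.random.default_rng(seed)
    yv = unfold(y)
    sst = float(np.sum((yv - yv.mean()) ** 2))
    selected: list[str] = []
    steps = []
    remaining = dict(candidates)

    def fit_r2(mats):
        D = np.column_stack([np.ones_like(yv)] + [unfold(m) for m in mats])
        res = yv - D @ (np.linalg.pinv(D) @ yv)
        return 1.0 - float(res @ res) / sst if sst > 0 else 0.0

    while remaining:
        base_mats = [candidates[k] for k in selected]
        base_r2 = fit_r2(base_mats) if selected else 0.0
        gains = {k: fit_r2(base_mats + [m]) - base_r2 for k, m in remaining.items()}
        best = max(gains, key=gains.get)
        # permutation p for the gain of the best candidate
        mats = base_mats + [remaining[best]]
        D = np.column_stack([np.ones_like(yv)] + [unfold(m) for m in mats])
        pinv = np.linalg.pinv(D)
        Db = np.column_stack([np.ones_like(yv)] + [unfold(m) for m in base_mats])
        pinvb = np.linalg.pinv(Db)
        gain_obs = gains[best]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            ypv = unfold(_permute_matrix(y, perm))
            sstp = float(np.sum((ypv - ypv.mean()) ** 2))
            if sstp <= 0:
                continue
            r_full = ypv - D @ (pinv @ ypv)
            r_base = ypv - Db @ (pinvb @ ypv)
            gain = (float(r_base @ r_base) - float(r_full @ r_full)) / sstp
            if gain >= gain_obs:
                count += 1
        p = (1 + count) / (n_perm + 1)
        if p <= p_enter and p_enter > 0:
            selected.append(best)
            steps.append({"name": best, "r2_gain": gain_obs, "p": p, "entered": True})
            del remaining[best]
        else:
            steps.append({"name": best, "r2_gain": gain_obs, "p": p, "entered": False})
            break
    final = None
    if selected:
        final = mrm(y, [candidates[k] for k in selected], selected,
                    n_perm=n_perm, seed=seed + 1)
    return steps, final


def partial_mantel(
    A: np.ndarray,
    B: np.ndarray,
    controls: list[np.ndarray] | None = None,
    control_names: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> MantelResult:
    """Partial (or simple) Mantel test.

    The partial correlation is the Pearson correlation between the
    unfolded residuals of A and B after each is regressed on the
    controls.  Significance comes from permuting the rows/columns of
    the residualized A matrix (residual-permutation method); with no
    controls this reduces to the simple Mantel test.
    """
    controls = list(controls or [])
    n = _check_square([A, B] + controls)
    for c in controls:
        if np.array_equal(c, A) or np.array_equal(c, B):
            raise ValueError("control identical to a tested matrix")
    av, bv = unfold(A), unfold(B)
    if controls:
        D = np.column_stack([np.ones_like(av)] + [unfold(c) for c in controls])
        pinv = np.linalg.pinv(D)
        ra = av - D @ (pinv @ av)
        rb = bv - D @ (pinv @ bv)
    else:
        ra, rb = av - av.mean(), bv - bv.mean()
    denom = np.sqrt(float(ra @ ra) * float(rb @ rb))
    r = float(ra @ rb) / denom if denom > 0 else 0.0
    # refold residualized A for matrix-preserving permutation
    Ares = np.zeros_like(A, dtype=float)
    idx = np.tril_indices(n, k=-1)
    Ares[idx] = ra
    Ares = Ares + Ares.T
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rap = unfold(_permute_matrix(Ares, perm))
        rap = rap - rap.mean()
        dn = np.sqrt(float(rap @ rap) * float(rb @ rb))
        rp = float(rap @ rb) / dn if dn > 0 else 0.0
        if alternative == "greater":
            count += rp >= r
        elif alternative == "less":
            count += rp <= r
        else:
            count += abs(rp) >= abs(r)
    return MantelResult(
        r, (1 + count) / (n_perm + 1), n_perm,
        control_names or [f"c{i + 1}" for i in range(len(controls))], seed,
    )


def cluster_distance_matrix(
    populations: list[str],
    cluster_labels: dict[str, str],
    admixed: set[str] | list[str] = (),
    admixed_value: float = 0.5,
) -> np.ndarray:
    """0/1 same/different-cluster dissimilarity matrix.

    Pairs within a cluster get 0, between clusters 1; pairs involving
    an admixed population get ``admixed_value`` (it belongs partly to
    both clusters), except admixed-admixed pairs which get 0.
    """
    P = len(populations)
    admixed = set(admixed)
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            a, b = populations[i], populations[j]
            if a in admixed and b in admixed:
                v = 0.0
            elif a in admixed or b in admixed:
                v = admixed_value
            elif cluster_labels[a] == cluster_labels[b]:
                v = 0.0
            else:
                v = 1.0
            out[i, j] = out[j, i] = v
    return out
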