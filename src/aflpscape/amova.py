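"""Analysis of molecular variance on band-frequency profiles.

Individual pairwise distances are squared-Euclidean style counts of
differing loci over jointly scored loci, rescaled to the full locus
count (``L * diff / shared``), which is unbiased under
missing-at-random scoring.  Variance components come from equating the
distance-based mean squares to their expectations with
unequal-sample-size coefficients; significance is by permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import BandMatrix

__all__ = ["AmovaResult", "amova", "pairwise_phist", "individual_distances"]


@dataclass
class AmovaResult:
    design: str                       # "two-level" | "three-level"
    ss: dict[str, float]
    df: dict[str, int]
    variance: dict[str, float]
    percent: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0


def individual_distances(m: BandMatrix) -> np.ndarray:
    """Squared distance between individual band profiles.

    ``d2[i, j] = L * (# loci with differing calls) / (# jointly scored
    loci)``.  Replicate rows are dropped first.
    """
    m = m.drop_replicates()
    X = m.values
    M = (~np.isnan(X)).astype(float)
    Xz = np.where(np.isnan(X), 0.0, X)
    shared = M @ M.T
    if (shared[~np.eye(len(shared), dtype=bool)] == 0).any():
        raise ValueError("individual pair with no jointly scored loci")
    a = Xz @ (M - Xz).T
    diff = a + a.T
    d2 = m.n_loci * diff / shared
    np.fill_diagonal(d2, 0.0)
    return d2


def _ss_within(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    """Sum over groups of (sum of pairwise d2 within)/group size."""
    tot = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        tot += sub.sum() / (2.0 * len(idx))
    return tot


def _components_two(d2, pop_idx):
    N = d2.shape[0]
    r = len(pop_idx)
    ss_total = d2.sum() / (2.0 * N)
    ss_wp = _ss_within(d2, pop_idx)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = r - 1, N - r
    sizes = np.array([len(i) for i in pop_idx], dtype=float)
    n_c = (N - (sizes ** 2).sum() / N) / (r - 1)
    ms_ap = ss_ap / df_ap
    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    var_w = ms_wp
    var_a = (ms_ap - var_w) / n_c
    return ss_total, ss_ap, ss_wp, df_ap, df_wp, var_a, var_w


def _components_three(d2, pop_idx, group_of_pop):
    N = d2.shape[0]
    P = len(pop_idx)
    glabels = sorted(set(group_of_pop))
    G = len(glabels)
    gidx = {
        g: np.concatenate([pop_idx[p] for p in range(P) if group_of_pop[p] == g])
        for g in glabels
    }
    ss_total = d2.sum() / (2.0 * N)
    ss_wp = _ss_within(d2, pop_idx)
    ss_wg = _ss_within(d2, [gidx[g] for g in glabels])
    ss_ap_wg = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    npg = np.array([len(i) for i in pop_idx], dtype=float)   # per pop
    ng = {g: len(gidx[g]) for g in glabels}
    # unequal-size coefficients (three-level nested ANOVA on distances)
    sum_sq_over_g = sum(
        sum(npg[p] ** 2 for p in range(P) if group_of_pop[p] == g) / ng[g]
        for g in glabels
    )
    n1 = (N - sum_sq_over_g) / df_ap
    n2 = (sum_sq_over_g - (npg ** 2).sum() / N) / df_ag
    n3 = (N - sum(v ** 2 for v in ng.values()) / N) / df_ag
    ms_ag = ss_ag / df_ag
    ms_ap = ss_ap_wg / df_ap if df_ap > 0 else 0.0
    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    var_c = ms_wp
    var_b = (ms_ap - var_c) / n1 if df_ap > 0 else 0.0
    var_a = (ms_ag - var_c - n2 * var_b) / n3
    return (ss_total, ss_ag, ss_ap_wg, ss_wp, df_ag, df_ap, df_wp,
            var_a, var_b, var_c)


def amova(
    m: BandMatrix,
    groups: dict[str, str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """AMOVA among populations, optionally nested in cluster groups.

    Without ``groups``: two-level design partitioning variance among
    populations (Phi_ST) vs within, with significance by permuting
    individuals among populations.  With ``groups`` (population ->
    cluster label): three-level design giving Phi_CT (among clusters;
    whole populations permuted among clusters), Phi_SC (among
    populations within clusters; individuals permuted among populations
    within their cluster) and Phi_ST (individuals permuted globally).
    P-values are ``(1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    rng = np.random.default_rng(seed)
    base = m.drop_replicates()
    d2 = individual_distances(base)
    pops = base.populations()
    pop_idx = [np.flatnonzero(np.asarray(base.population_ids) == p) for p in pops]
    N = d2.shape[0]

    if groups is None:
        ss_t, ss_ap, ss_wp, df_ap, df_wp, var_a, var_w = _components_two(d2, pop_idx)
        tot = var_a + var_w
        phi_st = var_a / tot if tot > 0 else 0.0
        res = AmovaResult(
            "two-level",
            {"among_pops": ss_ap, "within_pops": ss_wp, "total": ss_t},
            {"among_pops": df_ap, "within_pops": df_wp, "total": N - 1},
            {"among_pops": var_a, "within_pops": var_w},
            _percent({"among_pops": var_a, "within_pops": var_w}),
            {"Phi_ST": phi_st},
        )
        if n_perm > 0:
            sizes = [len(i) for i in pop_idx]
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(N)
                pidx, start = [], 0
                for s in sizes:
                    pidx.append(perm[start:start + s])
                    start += s
                *_, va, vw = _components_two(d2, pidx)
                t = va + vw
                if (va / t if t > 0 else 0.0) >= phi_st:
                    count += 1
            res.p_values["Phi_ST"] = (1 + count) / (n_perm + 1)
            res.n_permutations = n_perm
        return res

    group_of_pop = [groups[p] for p in pops]
    if len(set(group_of_pop)) < 2:
        raise ValueError("need at least two groups")
    for g in set(group_of_pop):
        if group_of_pop.count(g) < 2:
            import warnings
            warnings.warn(f"group {g!r} contains a single population; "
                          "Phi_SC is weakly identified there")
    (ss_t, ss_ag, ss_ap, ss_wp, df_ag, df_ap, df_wp,
     var_a, var_b, var_c) = _components_three(d2, pop_idx, group_of_pop)
    tot = var_a + var_b + var_c
    phi = {
        "Phi_CT": var_a / tot if tot > 0 else 0.0,
        "Phi_SC": var_b / (var_b + var_c) if (var_b + var_c) > 0 else 0.0,
        "Phi_ST": (var_a + var_b) / tot if tot > 0 else 0.0,
    }
    res = AmovaResult(
        "three-level",
        {"among_groups": ss_ag, "among_pops_within_groups": ss_ap,
         "within_pops": ss_wp, "total": ss_t},
        {"among_groups": df_ag, "among_pops_within_groups": df_ap,
         "within_pops": df_wp, "total": N - 1},
        {"among_groups": var_a, "among_pops_within_groups": var_b,
         "within_pops": var_c},
        _percent({"among_groups": var_a, "among_pops_within_groups": var_b,
                  "within_pops": var_c}),
        phi,
    )
    if n_perm > 0:
        res.p_values = _permute_three(
            d2, pop_idx, group_of_pop, phi, n_perm, rng
        )
        res.n_permutations = n_perm
    return res


def _percent(components: dict[str, float]) -> dict[str, float]:
    tot = sum(components.values())
    if tot <= 0:
        return {k: 0.0 for k in components}
    return {k: 100.0 * v / tot for k, v in components.items()}


def _phi_three(d2, pop_idx, group_of_pop):
    *_, va, vb, vc = _components_three(d2, pop_idx, group_of_pop)
    tot = va + vb + vc
    return (
        va / tot if tot > 0 else 0.0,
        vb / (vb + vc) if (vb + vc) > 0 else 0.0,
        (va + vb) / tot if tot > 0 else 0.0,
    )


def _permute_three(d2, pop_idx, group_of_pop, phi_obs, n_perm, rng):
    N = d2.shape[0]
    P = len(pop_idx)
    sizes = [len(i) for i in pop_idx]
    counts = {"Phi_CT": 0, "Phi_SC": 0, "Phi_ST": 0}
    glabels = sorted(set(group_of_pop))
    pops_in_g = {g: [p for p in range(P) if group_of_pop[p] == g] for g in glabels}
    for _ in range(n_perm):
        # Phi_CT: permute whole populations among groups
        perm_pops = rng.permutation(P)
        new_groups = [None] * P
        k = 0
        for g in glabels:
            for _p in pops_in_g[g]:
                new_groups[perm_pops[k]] = g
                k += 1
        ct, _, _ = _phi_three(d2, pop_idx, new_groups)
        if ct >= phi_obs["Phi_CT"]:
            counts["Phi_CT"] += 1
        # Phi_SC: permute individuals among populations within groups
        pidx_sc = [None] * P
        for g in glabels:
            members = np.concatenate([pop_idx[p] for p in pops_in_g[g]])
            shuffled = rng.permutation(members)
            start = 0
            for p in pops_in_g[g]:
                pidx_sc[p] = shuffled[start:start + sizes[p]]
                start += sizes[p]
        _, sc, _ = _phi_three(d2, pidx_sc, group_of_pop)
        if sc >= phi_obs["Phi_SC"]:
            counts["Phi_SC"] += 1
        # Phi_ST: permute individuals globally
        perm = rng.permutation(N)
        pidx_st, start = [], 0
        for s in sizes:
            pidx_st.append(perm[start:start + s])
            start += s
        _, _, st = _phi_three(d2, pidx_st, group_of_pop)
        if st >= phi_obs["Phi_ST"]:
            counts["Phi_ST"] += 1
    return {k: (1 + c) / (n_perm + 1) for k, c in counts.items()}


def pairwise_phist(m: BandMatrix) -> tuple[np.ndarray, list[str]]:
    """Two-population AMOVA Phi_ST for every population pair.

    Negative estimates are retained (clamping is a concern of the
    distance linearization downstream).
    """
    base = m.drop_replicates()
    d2 = individual_distances(base)
    pops = base.populations()
    pop_idx = [np.flatnonzero(np.asarray(base.population_ids) == p) for p in pops]
    P = len(pops)
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            idx = [pop_idx[i], pop_idx[j]]
            both = np.concatenate(idx)
            sub = d2[np.ix_(both, both)]
            local = [np.arange(len(pop_idx[i])),
                     np.arange(len(pop_idx[i]), len(both))]
            *_, va, vw = _components_two(sub, local)
            tot = va + vw
            out[i, j] = out[j, i] = va / tot if tot > 0 else 0.0
    return out, pops
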