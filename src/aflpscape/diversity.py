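"""Within-population diversity, Nei distances, and UPGMA trees.

All allele-frequency based statistics work from a
:class:`~aflpscape.datatypes.FrequencyTable` whose ``q_hat`` came from
the square-root HWE estimator (the convention of the common
dominant-marker diversity calculators).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import BandMatrix, FrequencyTable
from .estimators import band_frequencies

__all__ = [
    "percent_polymorphic",
    "unbiased_heterozygosity",
    "nei_distance_matrix",
    "upgma",
    "upgma_with_bootstrap",
    "TreeResult",
    "NEI_DISTANCE_CAP",
]

#: finite sentinel reported when two populations share no alleles
#: (Nei distance diverges to infinity)
NEI_DISTANCE_CAP = 1e3


def percent_polymorphic(freqs: FrequencyTable, level: float = 0.99) -> dict[str, float]:
    """Percentage of polymorphic loci per population.

    A locus counts as polymorphic in a population when its estimated
    presence-allele frequency lies strictly inside ``(1 - level,
    level)`` — e.g. the conventional "99% criterion" with the default.
    """
    out = {}
    p = freqs.p_hat
    for i, pop in enumerate(freqs.populations):
        scored = ~np.isnan(p[i])
        poly = (p[i][scored] > 1 - level) & (p[i][scored] < level)
        out[pop] = 100.0 * poly.sum() / scored.sum()
    return out


def unbiased_heterozygosity(freqs: FrequencyTable) -> dict[str, float]:
    """Unbiased expected heterozygosity (uHe) per population.

    Per locus ``He = 2 p q`` from the HWE allele-frequency estimates,
    corrected by ``2n / (2n - 1)`` with ``n`` the number of scored
    individuals; the population value is the mean over loci.  Loci with
    ``n <= 1`` in a population are skipped with a warning.
    """
    out = {}
    he = 2.0 * freqs.p_hat * freqs.q_hat
    skipped = 0
    for i, pop in enumerate(freqs.populations):
        n = freqs.n_eff[i].astype(float)
        ok = (n > 1) & ~np.isnan(he[i])
        skipped += int((n <= 1).sum())
        u = he[i][ok] * (2 * n[ok]) / (2 * n[ok] - 1)
        out[pop] = float(u.mean())
    if skipped > 0:
        warnings.warn(f"{skipped} population x locus cells with n_eff <= 1 skipped")
    return out


def nei_distance_matrix(freqs: FrequencyTable) -> np.ndarray:
    """Nei (1972) standard genetic distance between all population pairs.

    With biallelic loci: ``Jxy = sum(p_x p_y + q_x q_y)``,
    ``Jx = sum(p_x^2 + q_x^2)``, ``D = -ln(Jxy / sqrt(Jx Jy))``.
    Pairs with disjoint alleles at every locus (``Jxy = 0``) get the
    finite sentinel :data:`NEI_DISTANCE_CAP`.
    """
    p, q = freqs.p_hat, freqs.q_hat
    P = len(freqs.populations)
    D = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            shared = ~np.isnan(p[i]) & ~np.isnan(p[j])
            if not shared.any():
                raise ValueError(
                    f"populations {freqs.populations[i]!r} and "
                    f"{freqs.populations[j]!r} share no scored loci"
                )
            pi, pj = p[i][shared], p[j][shared]
            qi, qj = q[i][shared], q[j][shared]
            jxy = float(np.sum(pi * pj + qi * qj))
            jx = float(np.sum(pi ** 2 + qi ** 2))
            jy = float(np.sum(pj ** 2 + qj ** 2))
            if jxy <= 0:
                d = NEI_DISTANCE_CAP
            else:
                d = min(-np.log(jxy / np.sqrt(jx * jy)), NEI_DISTANCE_CAP)
            D[i, j] = D[j, i] = max(d, 0.0)
    return D


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class TreeResult:
    newick: str
    leaves: list[str]
    #: canonical bipartition (frozenset of the leaf subset below the
    #: node) -> bootstrap support percentage; None before bootstrapping
    supports: dict[frozenset, float] | None
    n_bootstrap: int


def _upgma_merge(D: np.ndarray, labels: list[str]):
    """Run UPGMA, returning (root node, bipartitions).

    Nodes are dicts {leaves, children, height}.  Tied merge heights are
    broken by the lexicographically smallest pair of cluster labels
    (each cluster keyed by its sorted leaf tuple).
    """
    D = D.astype(float).copy()
    nodes = [{"leaves": (lab,), "children": None, "height": 0.0} for lab in labels]
    sizes = np.ones(len(labels))
    active = list(range(len(labels)))
    biparts = []
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (
                    D[i, j],
                    tuple(sorted(nodes[i]["leaves"] + nodes[j]["leaves"])),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
        i, j = best[1], best[2]
        d = D[i, j]
        new = {
            "leaves": tuple(sorted(nodes[i]["leaves"] + nodes[j]["leaves"])),
            "children": (nodes[i], nodes[j]),
            "height": d / 2.0,
        }
        k = len(nodes)
        nodes.append(new)
        # average linkage update
        Dnew = np.full((k + 1, k + 1), np.inf)
        Dnew[:k, :k] = D
        for m in active:
            if m in (i, j):
                continue
            Dnew[k, m] = Dnew[m, k] = (
                sizes[i] * D[i, m] + sizes[j] * D[j, m]
            ) / (sizes[i] + sizes[j])
        D = Dnew
        sizes = np.append(sizes, sizes[i] + sizes[j])
        active = [m for m in active if m not in (i, j)] + [k]
        if 1 < len(new["leaves"]) < len(labels):
            biparts.append(frozenset(new["leaves"]))
    return nodes[active[0]], biparts


def _newick(node, parent_height, supports) -> str:
    if node["children"] is None:
        bl = parent_height - node["height"]
        return f"{node['leaves'][0]}:{bl:.6g}"
    left, right = node["children"]
    inner = ",".join(
        _newick(ch, node["height"], supports) for ch in (left, right)
    )
    label = ""
    if supports is not None:
        key = frozenset(node["leaves"])
        if key in supports:
            label = f"{supports[key]:.0f}"
    bl = parent_height - node["height"]
    return f"({inner}){label}:{bl:.6g}"


def upgma(D: np.ndarray, labels: list[str]) -> TreeResult:
    """UPGMA tree on a distance matrix; ties broken lexicographically."""
    if len(labels) < 3:
        raise ValueError("need at least 3 populations for a tree")
    root, biparts = _upgma_merge(D, labels)
    nwk = "(" + ",".join(_newick(ch, root["height"], None) for ch in root["children"]) + ");"
    return TreeResult(nwk, sorted(labels), {b: np.nan for b in biparts}, 0)


def upgma_with_bootstrap(
    m: BandMatrix, B: int = 1000, seed: int = 0
) -> TreeResult:
    """UPGMA on Nei distances with locus-resampling bootstrap supports.

    Each replicate resamples loci with replacement, recomputes the Nei
    distance matrix and tree, and scores which original bipartitions
    (internal-node leaf subsets) reappear.  Supports are percentages of
    ``B`` replicates; the tree text carries them as internal labels.
    """
    rng = np.random.default_rng(seed)
    freqs = band_frequencies(m)
    labels = freqs.populations
    if len(labels) < 3:
        raise ValueError("need at least 3 populations for a tree")
    D = nei_distance_matrix(freqs)
    root, biparts = _upgma_merge(D, labels)
    counts = {b: 0 for b in biparts}
    L = len(freqs.loci)
    for _ in range(B):
        idx = rng.integers(0, L, size=L)
        sub = FrequencyTable(
            labels, [freqs.loci[i] for i in idx],
            freqs.freq[:, idx], freqs.n_eff[:, idx], freqs.q_hat[:, idx],
            freqs.method,
        )
        Db = nei_distance_matrix(sub)
        _, bb = _upgma_merge(Db, labels)
        bset = set(bb)
        for b in counts:
            if b in bset:
                counts[b] += 1
    supports = {b: 100.0 * c / B for b, c in counts.items()}
    nwk = "(" + ",".join(
        _newick(ch, root["height"], supports) for ch in root["children"]
    ) + ");"
    return TreeResult(nwk, sorted(labels), supports, B)
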