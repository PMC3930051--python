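"""Synthetic dominant-marker datasets with known ground truth.

The generator emulates a small landscape-genetics survey: a handful of
populations sampled along a steep one-dimensional climatic gradient,
structured into two genetic clusters plus one admixed population,
genotyped at a few hundred anonymous dominant (band presence/absence)
loci, with a minority of loci under environment-driven divergent
selection and population phenotype means driven by environment plus one
trait-linked locus.

Population allele frequencies follow a two-level Balding-Nichols
cascade: each locus draws an ancestral presence-allele frequency
``p ~ Beta(a, b)``; each cluster draws
``p_c ~ Beta(p (1-F_CT)/F_CT, (1-p)(1-F_CT)/F_CT)`` and each population
within a cluster draws around ``p_c`` with ``F_SC``.  The admixed
population's frequency is the 50/50 mean of one donor population from
each cluster.  Individuals show a band with probability ``1 - q**2``
(Hardy-Weinberg dominance, ``q = 1 - p_pop``); within-population
inbreeding is assumed absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BandMatrix

__all__ = [
    "SimulationConfig",
    "SimFrequencies",
    "SyntheticDataset",
    "simulate_hierarchical_frequencies",
    "plant_selected_loci",
    "simulate_band_matrix",
    "simulate_environment",
    "simulate_phenotypes",
    "environment_scores",
    "simulate_dataset",
]

#: trait layout of the two common-garden style experiments.  The
#: net-house is insect-free and pot-grown, so field-response traits
#: (herbivory, pigmentation) are absent there and rosette metrics are
#: recorded instead.
NET_HOUSE_TRAITS = (
    "bolting_day", "flowering_day", "stalk_height", "stem_trichomes",
    "bud_trichomes", "rosette_diameter", "rosette_leaves", "inflorescences",
)
COMMON_GARDEN_TRAITS = (
    "bolting_day", "flowering_day", "stalk_height", "stem_trichomes",
    "bud_trichomes", "herbivory_early", "herbivory_late", "flower_pigmentation",
)

_DEFAULT_TRAIT_BASE = {
    "bolting_day": 55.0, "flowering_day": 70.0, "stalk_height": 60.0,
    "stem_trichomes": 1.5, "bud_trichomes": 1.5, "herbivory_early": 2.5,
    "herbivory_late": 2.5, "flower_pigmentation": 2.5,
    "rosette_diameter": 20.0, "rosette_leaves": 12.0, "inflorescences": 8.0,
}
# per-trait response to the standardized climate score (aridity up the
# gradient: earlier phenology, shorter plants, less herbivore damage)
_DEFAULT_ENV_COEFS = {
    "bolting_day": -6.0, "flowering_day": -6.0, "stalk_height": -8.0,
    "herbivory_early": -0.8, "herbivory_late": -0.8, "flower_pigmentation": 0.5,
    "rosette_diameter": -3.0, "rosette_leaves": -2.0, "inflorescences": -1.5,
    "stem_trichomes": 0.0, "bud_trichomes": 0.0,
}
_DEFAULT_NOISE_SD = {
    "bolting_day": 2.5, "flowering_day": 2.5, "stalk_height": 4.0,
    "stem_trichomes": 0.35, "bud_trichomes": 0.35, "herbivory_early": 0.4,
    "herbivory_late": 0.4, "flower_pigmentation": 0.3,
    "rosette_diameter": 1.5, "rosette_leaves": 1.0, "inflorescences": 1.0,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults match the emulated survey design.

    Nine populations (2 clusters x 4 + 1 admixed) of ~15 plants at 229
    dominant loci, cluster/population differentiation of roughly the
    magnitude a hierarchical AMOVA attributes 8%/6% of variance to,
    a few loci under divergent selection along the climate gradient,
    and a 0.78% genotyping error rate estimated from replicate pairs.
    """

    n_clusters: int = 2
    pops_per_cluster: int = 4
    n_admixed: int = 1
    n_individuals_per_pop: int = 15
    n_loci: int = 229
    F_CT: float = 0.08
    F_SC: float = 0.06
    ancestral_freq_prior: tuple[float, float] = (0.8, 0.8)
    n_selected_loci: int = 3
    selection_slope: float = 2.0
    env_gradient_strength: float = 1.0
    env_cross_corr: float = 0.5
    missing_rate: float = 0.02
    n_replicate_pairs: int = 15
    genotyping_error: float = 0.0078
    phenotype_env_coefs: dict = field(default_factory=lambda: dict(_DEFAULT_ENV_COEFS))
    phenotype_locus_coef: float = 3.0
    phenotype_locus_trait: str = "stem_trichomes"
    net_house_env_response: float = 0.0
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clusters", "pops_per_cluster", "n_individuals_per_pop", "n_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("F_CT", "F_SC"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("missing_rate", "genotyping_error"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_selected_loci > self.n_loci:
            raise ValueError("n_selected_loci exceeds n_loci")

    @property
    def n_populations(self) -> int:
        return self.n_clusters * self.pops_per_cluster + self.n_admixed

    def population_labels(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_populations)]

    def cluster_labels(self) -> list[str]:
        """Cluster label per population; admixed populations get their
        majority cluster (the first), flagged separately."""
        labels = []
        for c in range(self.n_clusters):
            labels += [f"C{c + 1}"] * self.pops_per_cluster
        labels += ["C1"] * self.n_admixed
        return labels

    def admixed_populations(self) -> list[str]:
        pops = self.population_labels()
        return pops[self.n_clusters * self.pops_per_cluster:]


@dataclass
class SimFrequencies:
    """True per-population presence-allele frequencies plus ancestry."""

    p_anc: np.ndarray          # (L,)
    cluster_freq: np.ndarray   # (C, L)
    pop_freq: np.ndarray       # (P, L)
    populations: list[str]
    clusters: list[str]


@dataclass
class SyntheticDataset:
    band_matrix: BandMatrix
    site_table: pd.DataFrame
    phenotypes: dict[str, pd.DataFrame]
    truth: dict


def _beta_around(rng: np.random.Generator, mean: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols draw around `mean` with differentiation F.

    F = 0 is the degenerate no-drift limit and returns `mean` itself.
    Means of exactly 0 or 1 stay fixed (Beta shape would be 0).
    """
    if F == 0:
        return mean.copy()
    scale = (1.0 - F) / F
    out = mean.copy()
    inner = (mean > 0) & (mean < 1)
    out[inner] = rng.beta(mean[inner] * scale, (1.0 - mean[inner]) * scale)
    return out


def simulate_hierarchical_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimFrequencies:
    """Draw the two-level Balding-Nichols frequency cascade."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    a, b = config.ancestral_freq_prior
    L = config.n_loci
    p_anc = rng.beta(a, b, size=L)
    C = config.n_clusters
    cluster_freq = np.vstack([_beta_around(rng, p_anc, config.F_CT) for _ in range(C)])
    pop_rows = []
    for c in range(C):
        for _ in range(config.pops_per_cluster):
            pop_rows.append(_beta_around(rng, cluster_freq[c], config.F_SC))
    # admixed populations: 50/50 mixture of one donor population per cluster
    donor_a = pop_rows[0]
    donor_b = pop_rows[config.pops_per_cluster] if C > 1 else pop_rows[0]
    for _ in range(config.n_admixed):
        pop_rows.append(0.5 * (donor_a + donor_b))
    return SimFrequencies(
        p_anc,
        cluster_freq,
        np.vstack(pop_rows),
        config.population_labels(),
        [f"C{c + 1}" for c in range(C)],
    )


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def plant_selected_loci(
    freqs: SimFrequencies,
    env_values: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SimFrequencies, dict]:
    """Overwrite a few loci with an environment-driven frequency cline.

    For each planted locus the population frequency becomes
    ``invlogit(logit(p_anc) + slope * env)``.  Candidate loci are drawn
    among those with intermediate ancestral frequency (0.2-0.8): near-
    fixed dominant loci carry almost no observable signal at realistic
    sample sizes, and selected markers enter real scans only if they
    were scorable/polymorphic in the first place.

    ``env_values`` must be standardized (mean ~0, sd ~1) per population.
    Returns the modified frequencies and a truth record.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    env = np.asarray(env_values, dtype=float)
    if env.shape[0] != freqs.pop_freq.shape[0]:
        raise ValueError("env_values length must equal number of populations")
    if config.n_selected_loci > config.n_loci:
        raise ValueError("more selected loci than loci")
    eligible = np.flatnonzero((freqs.p_anc >= 0.2) & (freqs.p_anc <= 0.8))
    if eligible.size < config.n_selected_loci:
        eligible = np.arange(config.n_loci)
    sel = np.sort(rng.choice(eligible, size=config.n_selected_loci, replace=False))
    out = SimFrequencies(
        freqs.p_anc.copy(), freqs.cluster_freq.copy(), freqs.pop_freq.copy(),
        list(freqs.populations), list(freqs.clusters),
    )
    for loc in sel:
        out.pop_freq[:, loc] = _invlogit(_logit(freqs.p_anc[loc]) + config.selection_slope * env)
    truth = {
        "selected_loci": [int(i) for i in sel],
        "selection_slope": config.selection_slope,
        "trait_locus": int(sel[0]) if len(sel) else None,
        "trait": config.phenotype_locus_trait,
        "phenotype_locus_coef": config.phenotype_locus_coef,
        "F_CT": config.F_CT,
        "F_SC": config.F_SC,
        "seed": config.seed,
        "env_values": [float(v) for v in env],
    }
    return out, truth


def simulate_band_matrix(
    freqs: SimFrequencies,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> BandMatrix:
    """Sample individual band phenotypes from population frequencies.

    Each individual shows a band with probability ``1 - q**2`` (HWE
    dominance).  Entries are masked missing independently at
    ``missing_rate``.  ``n_replicate_pairs`` individuals (spread
    round-robin over populations) are duplicated with an independent
    per-locus flip probability ``genotyping_error``; the duplicate's id
    is the original's with a ``_rep`` suffix and carries a
    ``replicate_of`` annotation.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    P, L = freqs.pop_freq.shape
    n = config.n_individuals_per_pop
    band_p = 1.0 - (1.0 - freqs.pop_freq) ** 2
    ids, pops, rows = [], [], []
    for j, pop in enumerate(freqs.populations):
        draws = (rng.random((n, L)) < band_p[j]).astype(float)
        rows.append(draws)
        ids += [f"{pop}-{k + 1}" for k in range(n)]
        pops += [pop] * n
    values = np.vstack(rows)
    if config.missing_rate > 0:
        values[rng.random(values.shape) < config.missing_rate] = np.nan
    reps: list[str | None] = [None] * len(ids)
    rep_vals, rep_ids, rep_pops = [], [], []
    for k in range(config.n_replicate_pairs):
        pop_i = k % P
        src_row = pop_i * n + (k // P) % n
        src = values[src_row].copy()
        flips = rng.random(L) < config.genotyping_error
        scored = ~np.isnan(src)
        src[scored & flips] = 1.0 - src[scored & flips]
        rep_vals.append(src)
        rep_ids.append(f"{ids[src_row]}_rep")
        rep_pops.append(pops[src_row])
        reps.append(ids[src_row])
    if rep_vals:
        values = np.vstack([values] + [v[None, :] for v in rep_vals])
        ids += rep_ids
        pops += rep_pops
    loci = [f"L{j + 1:03d}" for j in range(L)]
    return BandMatrix(values, ids, pops, loci, reps)


def simulate_environment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Site table: populations along a latitude gradient.

    Climatic variables are linear in latitude (scaled by
    ``env_gradient_strength``) plus noise; edaphic variables follow a
    second gradient correlated with the climatic one at
    ``env_cross_corr``.  Raw variables are returned, not PCA scores.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    P = config.n_populations
    pops = config.population_labels()
    # order populations north (cluster 1) to south, admixed at the border
    lat = np.linspace(32.8, 31.9, P)
    order = _gradient_order(config)
    lat_z = (lat - lat.mean()) / lat.std()
    g = config.env_gradient_strength
    # climatic block: south = hotter, drier, lower
    s = -lat_z  # aridity increases southwards
    temp = 12.8 + 1.0 * g * s + rng.normal(0, 0.25, P)
    rain = 300.0 - 115.0 * g * s + rng.normal(0, 30.0, P)
    alt = -150.0 - 120.0 * g * s + rng.normal(0, 90.0, P)
    slope = np.abs(rng.normal(5, 3, P))
    aspect = rng.uniform(0, 360, P)
    # edaphic block: correlated with the climate gradient at rho
    rho = config.env_cross_corr if g > 0 else 0.0
    e = rho * s + np.sqrt(max(1 - rho ** 2, 0.0)) * rng.normal(0, 1, P)
    ec = np.clip(1.2 + 0.8 * e + rng.normal(0, 0.25, P), 0.05, None)
    ph = 7.6 + 0.15 * e + rng.normal(0, 0.1, P)
    caco3 = np.clip(25 + 10 * e + rng.normal(0, 4, P), 0.5, None)
    ssa = np.clip(85 + 30 * e + rng.normal(0, 10, P), 5, None)
    hmc = 0.025 * ssa + 0.488 + rng.normal(0, 0.05, P)
    loi = np.clip(6 + rng.normal(0, 1.5, P), 0.5, None)
    stoniness = np.clip(20 - 8 * e + rng.normal(0, 4, P), 0.0, None)
    df = pd.DataFrame({
        "population": pops,
        "latitude": lat[order],
        "longitude": 35.5 + rng.normal(0, 0.05, P),
        "altitude": alt[order],
        "mean_temp": temp[order],
        "rainfall": rain[order],
        "slope": slope,
        "aspect": aspect,
        "EC": ec[order],
        "pH": ph[order],
        "CaCO3": caco3[order],
        "HMC": hmc[order],
        "SSA": ssa[order],
        "LOI": loi[order],
        "stoniness": stoniness[order],
    })
    return df


def _gradient_order(config: SimulationConfig) -> np.ndarray:
    """Map gradient positions to population indices.

    Cluster 1 populations sit at the north end, cluster 2 at the south,
    and admixed populations at the contact zone in between; within the
    returned array, entry k is the gradient position of population k.
    """
    P = config.n_populations
    k = config.pops_per_cluster
    if config.n_clusters != 2:
        return np.arange(P)
    order = np.empty(P, dtype=int)
    order[:k] = np.arange(k)              # cluster 1: north end
    order[k:2 * k] = np.arange(P - k, P)  # cluster 2: south end
    mid = list(range(k, P - k)) or [P // 2]
    for i in range(config.n_admixed):
        order[2 * k + i] = mid[i % len(mid)]
    return order


def environment_scores(site_table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Standardized climate and edaphic composite scores per population.

    The climate score averages z-scored temperature and (negated)
    rainfall — i.e. aridity; the edaphic score averages z-scored EC,
    CaCO3 and SSA.  Both re-standardized to mean 0, sd 1.
    """
    def z(x):
        x = np.asarray(x, dtype=float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    climate = z(z(site_table["mean_temp"]) - z(site_table["rainfall"]))
    edaphic = z(z(site_table["EC"]) + z(site_table["CaCO3"]) + z(site_table["SSA"]))
    return climate, edaphic


def simulate_phenotypes(
    site_table: pd.DataFrame,
    freqs: SimFrequencies,
    truth: dict,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Population trait means for the two experiments.

    Each trait mean is ``base + coef * climate_score +
    locus_coef * band_freq(trait locus) + Normal(0, noise_sd)``.  The
    net-house experiment scales its environment-response coefficients by
    ``net_house_env_response`` (0 by default: a controlled, insect-free
    environment expresses no field response), mirroring the plasticity
    contrast between the two experiments.  Ordinal scores are clipped to
    their scales (trichomes/herbivory 0-5, pigmentation 1-4).
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    climate, _ = environment_scores(site_table)
    loc = truth.get("trait_locus")
    band = None
    if loc is not None and config.phenotype_locus_coef != 0:
        f = freqs.pop_freq[:, loc]
        band = 1.0 - (1.0 - f) ** 2
    out = {}
    for exp, traits in (("net_house", NET_HOUSE_TRAITS), ("common_garden", COMMON_GARDEN_TRAITS)):
        env_scale = config.net_house_env_response if exp == "net_house" else 1.0
        data = {"population": list(site_table["population"])}
        for t in traits:
            coef = config.phenotype_env_coefs.get(t, 0.0) * env_scale
            mu = _DEFAULT_TRAIT_BASE[t] + coef * climate
            if band is not None and t == truth.get("trait"):
                mu = mu + config.phenotype_locus_coef * band
            sd = config.noise_sd.get(t, 0.0) if isinstance(config.noise_sd, dict) else config.noise_sd
            vals = mu + rng.normal(0, sd, len(mu)) if sd > 0 else mu.astype(float)
            if "trichome" in t or "herbivory" in t:
                vals = np.clip(vals, 0, 5)
            elif t == "flower_pigmentation":
                vals = np.clip(vals, 1, 4)
            data[t] = vals
        df = pd.DataFrame(data)
        df["experiment"] = exp
        out[exp] = df
    return out


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator chain with one seeded RNG stream."""
    rng = np.random.default_rng(config.seed)
    site = simulate_environment(config, rng)
    climate, _ = environment_scores(site)
    freqs = simulate_hierarchical_frequencies(config, rng)
    if config.n_selected_loci > 0:
        freqs, truth = plant_selected_loci(freqs, climate, config, rng)
    else:
        truth = {
            "selected_loci": [], "selection_slope": config.selection_slope,
            "trait_locus": None, "trait": config.phenotype_locus_trait,
            "phenotype_locus_coef": config.phenotype_locus_coef,
            "F_CT": config.F_CT, "F_SC": config.F_SC, "seed": config.seed,
            "env_values": [float(v) for v in climate],
        }
    m = simulate_band_matrix(freqs, config, rng)
    truth["pop_freq"] = [[float(v) for v in row] for row in freqs.pop_freq]
    truth["clusters"] = {p: c for p, c in zip(config.population_labels(), config.cluster_labels())}
    truth["admixed"] = config.admixed_populations()
    phen = simulate_phenotypes(site, freqs, truth, config, rng)
    return SyntheticDataset(m, site, phen, truth)
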