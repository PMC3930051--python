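"""Core in-memory containers shared by every analysis stage.

Dominant markers (AFLP bands) are scored per individual as band present
(1) or absent (0); a band-absent individual is homozygous for the
recessive "null" allele.  Throughout the package the presence allele has
frequency ``p`` and the null allele ``q = 1 - p``, so under
Hardy-Weinberg equilibrium the expected band frequency is ``1 - q**2``.

Site, phenotype and similar per-population tables are plain
:class:`pandas.DataFrame` objects with a ``population`` column; only the
two containers with non-trivial invariants get dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BandMatrix", "FrequencyTable", "MISSING_CODE"]

#: default on-disk code for a missing (unscorable) band call
MISSING_CODE = "-9"


@dataclass
class BandMatrix:
    """Individuals x loci binary dominant-marker matrix.

    Parameters
    ----------
    values
        Float array of shape (n_individuals, n_loci); entries are 0.0,
        1.0 or ``nan`` for missing.
    individual_ids, population_ids, locus_names
        Row labels, population label per row, column labels.
    replicate_of
        Optional per-row label: the id of the individual this row is a
        re-genotyped replicate of (``None`` for ordinary rows).
    """

    values: np.ndarray
    individual_ids: list[str]
    population_ids: list[str]
    locus_names: list[str]
    replicate_of: list[str | None] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = list(self.individual_ids)
        self.population_ids = list(self.population_ids)
        self.locus_names = list(self.locus_names)
        if self.replicate_of is None:
            self.replicate_of = [None] * len(self.individual_ids)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n, L = self.values.shape
        if len(self.individual_ids) != n or len(self.population_ids) != n:
            raise ValueError("row label length does not match matrix")
        if len(self.locus_names) != L:
            raise ValueError("locus label length does not match matrix")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        ok = np.isnan(self.values) | (self.values == 0) | (self.values == 1)
        if not ok.all():
            raise ValueError("band matrix entries must be 0, 1 or missing")
        for pop in self.populations():
            if self.population_ids.count(pop) < 2:
                raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        if (np.isnan(self.values).all(axis=0)).any():
            raise ValueError("locus with no non-missing entries")

    # -- convenience ---------------------------------------------------
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population_ids:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self) -> dict[str, np.ndarray]:
        pops = np.asarray(self.population_ids)
        return {p: np.flatnonzero(pops == p) for p in self.populations()}

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def drop_replicates(self) -> "BandMatrix":
        """Return a copy without replicate rows (for population statistics)."""
        keep = [i for i, r in enumerate(self.replicate_of) if r is None]
        return BandMatrix(
            self.values[keep],
            [self.individual_ids[i] for i in keep],
            [self.population_ids[i] for i in keep],
            list(self.locus_names),
            [None] * len(keep),
        )

    def subset_loci(self, idx) -> "BandMatrix":
        idx = np.asarray(idx)
        return BandMatrix(
            self.values[:, idx],
            list(self.individual_ids),
            list(self.population_ids),
            [self.locus_names[i] for i in idx],
            list(self.replicate_of),
        )


@dataclass
class FrequencyTable:
    """Per-population, per-locus band and allele frequency estimates.

    ``freq`` is the observed band frequency (fraction of non-missing
    individuals showing the band); ``q_hat`` the estimated null-allele
    frequency and ``p_hat = 1 - q_hat`` the presence-allele frequency.
    ``n_eff`` counts the non-missing individuals behind each cell.
    """

    populations: list[str]
    loci: list[str]
    freq: np.ndarray        # (P, L)
    n_eff: np.ndarray       # (P, L) int
    q_hat: np.ndarray       # (P, L)
    method: str = "sqrt"

    @property
    def p_hat(self) -> np.ndarray:
        return 1.0 - self.q_hat

    def __post_init__(self) -> None:
        P, L = self.freq.shape
        if len(self.populations) != P or len(self.loci) != L:
            raise ValueError("labels do not match frequency array")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.q_hat) < -1e-12 or np.nanmax(self.q_hat) > 1 + 1e-12:
                raise ValueError("q_hat outside [0, 1]")
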