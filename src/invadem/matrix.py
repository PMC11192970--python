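"""In-memory container for diploid biallelic SNP genotypes.

Genotypes are stored as an individuals x loci ``int8`` array of minor/alt
allele dosages: 0, 1, 2, with -1 for a missing call.  Every individual
carries a population label; populations may carry geographic coordinates
(latitude, longitude in decimal degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid biallelic calls for individuals x loci.

    Parameters
    ----------
    calls
        ``(n_ind, n_loci)`` int8 array with entries in {0, 1, 2, -1}.
    individual_ids, locus_ids
        Unique string identifiers, one per row / column.
    pop_labels
        Population name per individual (parallel to ``individual_ids``).
    coords
        Optional mapping population -> (lat, lon).
    """

    calls: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    pop_labels: list[str]
    coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x loci)")
        n_ind, n_loci = self.calls.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length mismatch")
        if len(self.locus_ids) != n_loci:
            raise ValueError("locus_ids length mismatch")
        if len(self.pop_labels) != n_ind:
            raise ValueError("every individual needs a population label")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls restricted to {0, 1, 2, -1}")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.pop_labels) == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population {pop!r}")
        return idx

    def restrict(self, individuals: np.ndarray | None = None,
                 loci: np.ndarray | None = None) -> "GenotypeMatrix":
        """Row/column subset, returned as a new matrix."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        loc = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            calls=self.calls[np.ix_(ind, loc)],
            individual_ids=[self.individual_ids[i] for i in ind],
            locus_ids=[self.locus_ids[j] for j in loc],
            pop_labels=[self.pop_labels[i] for i in ind],
            coords=dict(self.coords),
        )

    def for_population(self, pop: str) -> "GenotypeMatrix":
        return self.restrict(individuals=self.pop_indices(pop))

    # ------------------------------------------------------------------
    def allele_counts(self, pop: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (alt copies, called copies) over a population or everyone."""
        sub = self.calls if pop is None else self.calls[self.pop_indices(pop)]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def allele_freqs(self, pop: str | None = None) -> np.ndarray:
        """Per-locus alt frequency; NaN where no calls."""
        alt, tot = self.allele_counts(pop)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def missing_rate_per_individual(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"GenotypeMatrix({self.n_individuals} individuals x "
                f"{self.n_loci} loci, {len(self.populations)} populations)")
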