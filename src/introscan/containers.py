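"""Core in-memory containers shared by every analysis module.

Coordinates are 0-based half-open internally; VCF/GFF readers and writers
convert from/to the 1-based inclusive conventions of those formats at the
I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = np.nan

#: columns every site table carries
SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "is_biallelic_snp"]


@dataclass
class GenotypeMatrix:
    """Samples x sites alt-allele dosage matrix with a per-site table.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows of ``dosage``).
    sites
        DataFrame with columns ``chrom, pos, ref, alt, qual,
        is_biallelic_snp``; ``pos`` is 0-based. Sorted by (chrom, pos).
    dosage
        ``(n_samples, n_sites)`` float array holding the number of alt
        allele copies per call: 0, 1, 2 or NaN for a missing genotype.
    contig_lengths
        Optional chromosome lengths (bp), used for window tiling.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"site table lacks columns: {missing}")
        valid = np.isin(self.dosage, (0.0, 1.0, 2.0)) | np.isnan(self.dosage)
        if not valid.all():
            raise ValueError("dosage values must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given site positions.

        ``index`` may be a boolean mask or an integer index array; order of
        retained sites is preserved.
        """
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            contig_lengths=dict(self.contig_lengths),
        )

    def take_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites.copy(),
            dosage=self.dosage[idx],
            contig_lengths=dict(self.contig_lengths),
        )


@dataclass
class PopulationMap:
    """Sample -> population assignment with optional per-population roles.

    Roles name the slot a population plays in a polarized analysis:
    ``P1``, ``P2``, ``P3``, ``hybrid`` or ``outgroup``.
    """

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    VALID_ROLES = frozenset({"P1", "P2", "P3", "hybrid", "outgroup"})

    def __post_init__(self) -> None:
        bad = set(self.roles.values()) - self.VALID_ROLES
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == population]
        if not out:
            raise KeyError(f"population {population!r} has no samples")
        return out

    def population_for_role(self, role: str) -> str | None:
        for pop, r in self.roles.items():
            if r == role:
                return pop
        return None


@dataclass
class FrequencyTable:
    """Per-site derived/alt allele frequency for each population.

    ``freqs[pop]`` is an array of length ``n_sites``; NaN marks a site with
    zero called alleles in that population. ``sites`` optionally carries
    the matching site table (chrom/pos) so windowed statistics can report
    genomic spans.
    """

    freqs: dict[str, np.ndarray]
    sites: pd.DataFrame | None = None
    n_called: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.freqs.values()}
        if len(lengths) > 1:
            raise ValueError("population frequency arrays differ in length")
        for pop, arr in self.freqs.items():
            arr = np.asarray(arr, dtype=float)
            with np.errstate(invalid="ignore"):
                if np.nanmin(arr, initial=0.0) < 0 or np.nanmax(arr, initial=0.0) > 1:
                    raise ValueError(f"frequencies for {pop!r} outside [0, 1]")
            self.freqs[pop] = arr

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.freqs.values()))) if self.freqs else 0

    @property
    def populations(self) -> list[str]:
        return list(self.freqs)

    def usable(self, populations: Sequence[str]) -> np.ndarray:
        """Boolean mask of sites with a defined frequency in every listed
        population."""
        mask = np.ones(self.n_sites, dtype=bool)
        for pop in populations:
            mask &= np.isfinite(self.freqs[pop])
        return mask


def dosage_frequency(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt allele frequency and called-allele count from a dosage block.

    ``dosage`` has shape ``(n_samples, n_sites)``; missing entries are NaN
    and are excluded from both numerator and denominator.
    """
    called = np.isfinite(dosage)
    n_alleles = 2 * called.sum(axis=0).astype(float)
    alt = np.where(called, dosage, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, alt / n_alleles, np.nan)
    return freq, n_alleles
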