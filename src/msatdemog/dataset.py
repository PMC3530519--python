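"""Core containers for diploid microsatellite genotype data.

Allele calls are stored in *repeat units* (integer allele sizes on the
stepwise-mutation lattice), not in raw fragment-length codes.  The
conversion between Genepop allele codes and repeat units is an affine
map held per locus by :class:`LocusDef`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Sentinel for a missing allele call (both alleles of a diploid call are
#: set to MISSING together; half-missing calls are promoted to missing).
MISSING: float = np.nan


@dataclass(frozen=True)
class LocusDef:
    """Definition of one microsatellite locus.

    Parameters
    ----------
    name
        Locus label.
    motif_length
        Base pairs per repeat unit (>= 1).
    coding
        Digit width of the Genepop allele code (2 or 3).
    offset
        Fragment-length code of the size-0 allele; codes map to repeat
        units by ``size = (code - offset) / motif_length`` and back by
        ``code = offset + motif_length * size``.
    """

    name: str
    motif_length: int = 1
    coding: int = 3
    offset: int = 500

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")
        if self.coding not in (2, 3):
            raise ValueError(f"coding must be 2 or 3, got {self.coding}")

    def code_to_size(self, code: int) -> int:
        """Convert an integer Genepop allele code to repeat units."""
        delta = code - self.offset
        if delta % self.motif_length != 0:
            raise ValueError(
                f"locus {self.name}: code {code} is not on the "
                f"motif-{self.motif_length} lattice with offset {self.offset}"
            )
        return delta // self.motif_length

    def size_to_code(self, size: int) -> int:
        """Convert repeat units back to an integer Genepop allele code."""
        code = self.offset + self.motif_length * int(size)
        if not 0 < code < 10**self.coding:
            raise ValueError(
                f"locus {self.name}: allele size {size} maps to code {code}, "
                f"unencodable at {self.coding}-digit coding"
            )
        return code


@dataclass
class GenotypeDataset:
    """Diploid microsatellite genotypes with population metadata.

    Attributes
    ----------
    individuals
        Unique individual identifiers, length ``n``.
    loci
        Locus definitions, length ``L``.
    calls
        Array ``(n, L, 2)`` of allele sizes in repeat units; ``NaN`` marks
        a missing call (always both alleles at once).
    population
        Population label per individual.
    deme
        Optional sub-population label per individual.
    sample_year
        Optional collection year per individual.
    """

    individuals: list[str]
    loci: list[LocusDef]
    calls: np.ndarray
    population: np.ndarray
    deme: Optional[np.ndarray] = None
    sample_year: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.population = np.asarray(self.population, dtype=object)
        if self.deme is not None:
            self.deme = np.asarray(self.deme, dtype=object)
        if self.sample_year is not None:
            self.sample_year = np.asarray(self.sample_year)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci x 2"
            )
        if len(set(self.individuals)) != n:
            raise ValueError("individual IDs are not unique")
        if self.population.shape != (n,):
            raise ValueError("population labels must be one per individual")
        if any(not str(p) for p in self.population):
            raise ValueError("population labels must be non-empty")
        if self.deme is not None and self.deme.shape != (n,):
            raise ValueError("deme labels must be one per individual")
        if self.sample_year is not None and self.sample_year.shape != (n,):
            raise ValueError("sample_year must be one per individual")
        # a call is either fully missing or fully present
        half = np.isnan(self.calls).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing diploid call found; promote to missing")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(str(p), None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array: True where the call is missing."""
        return np.isnan(self.calls[:, :, 0])

    def typed_loci_per_individual(self) -> np.ndarray:
        return (~self.missing_mask()).sum(axis=1)

    # ------------------------------------------------------------------
    def subset(self, mask: Sequence[bool] | np.ndarray) -> "GenotypeDataset":
        """Row-subset of individuals (boolean mask or index array)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeDataset(
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
            population=self.population[idx].copy(),
            deme=None if self.deme is None else self.deme[idx].copy(),
            sample_year=None
            if self.sample_year is None
            else self.sample_year[idx].copy(),
        )

    def select(self, population: Optional[str] = None, deme: Optional[str] = None) -> "GenotypeDataset":
        """Slice by population and/or deme label."""
        mask = np.ones(self.n_individuals, dtype=bool)
        if population is not None:
            if population not in set(map(str, self.population)):
                raise KeyError(f"unknown population label {population!r}")
            mask &= np.array([str(p) == population for p in self.population])
        if deme is not None:
            if self.deme is None:
                raise KeyError("dataset carries no deme labels")
            if deme not in set(map(str, self.deme)):
                raise KeyError(f"unknown deme label {deme!r}")
            mask &= np.array([str(d) == deme for d in self.deme])
        return self.subset(mask)

    def drop_loci(self, names: Sequence[str]) -> "GenotypeDataset":
        keep = [i for i, l in enumerate(self.loci) if l.name not in set(names)]
        return replace(
            self,
            loci=[self.loci[i] for i in keep],
            calls=self.calls[:, keep, :].copy(),
        )

    def sizes_at_locus(self, locus: int) -> np.ndarray:
        """Non-missing allele sizes (gene copies) at one locus, flattened."""
        vals = self.calls[:, locus, :].ravel()
        return vals[~np.isnan(vals)].astype(int)
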