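"""Core in-memory containers shared by the observed-data and simulation paths.

A study dataset couples three pieces: a diploid microsatellite genotype
matrix, an optional haploid (mitochondrial) sequence alignment, and a
partition of individuals into populations, optionally nested in groups.
Simulated datasets use exactly the same containers, so every statistic is
computed by one code path regardless of origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SequenceAlignment",
    "MsatGenotypeMatrix",
    "PopulationPartition",
    "PopulationDataset",
    "MISSING",
]

#: sentinel allele value for a missing genotype
MISSING: int = -1

_VALID_CHARS = set("ACGTN-")


class SequenceAlignment:
    """Equal-length nucleotide sequences over the alphabet {A,C,G,T,N,-}.

    Sequences are stored as an (n, L) byte matrix for fast column-wise
    statistics; gaps and Ns are treated as missing data site-wise.
    """

    def __init__(self, sequences: Sequence[str], ids: Sequence[str] | None = None):
        if len(sequences) == 0:
            raise ValueError("alignment needs at least one sequence")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        L = lengths.pop()
        if L == 0:
            raise ValueError("alignment length must be positive")
        upper = [s.upper() for s in sequences]
        bad = set("".join(upper)) - _VALID_CHARS
        if bad:
            raise ValueError(f"invalid characters in alignment: {sorted(bad)}")
        self._matrix = np.frombuffer(
            "".join(upper).encode("ascii"), dtype="S1"
        ).reshape(len(upper), L)
        if ids is None:
            ids = [f"seq{i}" for i in range(len(upper))]
        if len(ids) != len(upper):
            raise ValueError("ids and sequences differ in length")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        self.ids: list[str] = list(ids)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self._matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self._matrix.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """(n, L) array of single-byte characters."""
        return self._matrix

    def sequence(self, i: int) -> str:
        return self._matrix[i].tobytes().decode("ascii")

    def valid_mask(self) -> np.ndarray:
        """(n, L) boolean array, True where the base is one of A/C/G/T."""
        m = self._matrix
        return (m != b"N") & (m != b"-")

    def subset(self, indices: Iterable[int]) -> "SequenceAlignment":
        idx = list(indices)
        return SequenceAlignment(
            [self.sequence(i) for i in idx], [self.ids[i] for i in idx]
        )

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"ids not in alignment: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)


class MsatGenotypeMatrix:
    """Diploid microsatellite genotypes: individuals x loci x 2 allele sizes.

    Allele sizes are positive integers (repeat counts); ``MISSING`` (-1 in
    both slots) marks an untyped genotype.  Genotypes are unordered pairs —
    the two slots carry no phase information.
    """

    def __init__(
        self,
        alleles: np.ndarray,
        individual_ids: Sequence[str],
        locus_ids: Sequence[str] | None = None,
    ):
        alleles = np.asarray(alleles, dtype=np.int64)
        if alleles.ndim != 3 or alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        n, L, _ = alleles.shape
        if n < 1 or L < 1:
            raise ValueError("need at least one individual and one locus")
        half_missing = (alleles == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("half-missing genotypes are not allowed")
        if ((alleles != MISSING) & (alleles < 1)).any():
            raise ValueError("allele sizes must be positive integers")
        if len(individual_ids) != n:
            raise ValueError("individual_ids length mismatch")
        if len(set(individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if locus_ids is None:
            locus_ids = [f"locus{j + 1}" for j in range(L)]
        if len(locus_ids) != L:
            raise ValueError("locus_ids length mismatch")
        self.alleles = alleles
        self.individual_ids = list(individual_ids)
        self.locus_ids = list(locus_ids)

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean, True where the genotype is missing."""
        return self.alleles[:, :, 0] == MISSING

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.individual_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"ids not in genotype matrix: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def subset(self, indices: Iterable[int]) -> "MsatGenotypeMatrix":
        idx = np.asarray(list(indices), dtype=np.intp)
        return MsatGenotypeMatrix(
            self.alleles[idx], [self.individual_ids[i] for i in idx], self.locus_ids
        )


@dataclass
class PopulationPartition:
    """Assignment of individuals to populations, optionally nested in groups."""

    individual_to_population: dict[str, str]
    population_to_group: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.individual_to_population:
            raise ValueError("partition is empty")
        if self.population_to_group is not None:
            pops = set(self.individual_to_population.values())
            unmapped = pops - set(self.population_to_group)
            if unmapped:
                raise ValueError(f"populations without group: {sorted(unmapped)}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.individual_to_population.values():
            seen.setdefault(p, None)
        return list(seen)

    @property
    def groups(self) -> list[str] | None:
        if self.population_to_group is None:
            return None
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(self.population_to_group[p], None)
        return list(seen)

    def members(self, population: str) -> list[str]:
        return [
            i
            for i, p in self.individual_to_population.items()
            if p == population
        ]

    def group_members(self, group: str) -> list[str]:
        if self.population_to_group is None:
            raise ValueError("partition has no groups")
        return [
            i
            for i, p in self.individual_to_population.items()
            if self.population_to_group[p] == group
        ]

    def group_of(self, individual: str) -> str:
        if self.population_to_group is None:
            raise ValueError("partition has no groups")
        return self.population_to_group[self.individual_to_population[individual]]

    def as_group_partition(self) -> "PopulationPartition":
        """Collapse populations into their groups (group becomes population)."""
        if self.population_to_group is None:
            raise ValueError("partition has no groups")
        return PopulationPartition(
            {
                i: self.population_to_group[p]
                for i, p in self.individual_to_population.items()
            }
        )


@dataclass
class PopulationDataset:
    """One observed or simulated study: genotypes + sequences + partition.

    ``sequences`` may be None for a microsatellite-only analysis.  Sequence
    ids must be a subset of genotype individual ids when both are present
    (one maternal haplotype per sampled individual).
    """

    genotypes: MsatGenotypeMatrix
    partition: PopulationPartition
    sequences: SequenceAlignment | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = set(self.genotypes.individual_ids)
        assigned = set(self.partition.individual_to_population)
        if ids - assigned:
            raise ValueError(
                f"individuals without population: {sorted(ids - assigned)[:5]}"
            )
        if self.sequences is not None:
            extra = set(self.sequences.ids) - ids
            if extra:
                raise ValueError(
                    f"sequence ids not among individuals: {sorted(extra)[:5]}"
                )
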