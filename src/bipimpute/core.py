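"""Core data model for biparental phasing and imputation.

Genotypes are coded 0, 1, 2 (0 and 2 the two homozygotes, 1 the
heterozygote) with 9 as the missing sentinel.  Haplotype alleles are coded
0/1 (allele 1 is the one counted by the genotype code, so a genotype equals
the sum of its two haplotype alleles) with 9 again meaning missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import TopologicalSorter
from typing import Iterable

import numpy as np

#: missing-value sentinel used throughout (genotype and allele arrays)
MISSING = 9

VALID_GENOTYPES = frozenset({0, 1, 2, MISSING})
VALID_ALLELES = frozenset({0, 1, MISSING})


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of genotype codes {0,1,2,9}.

    Row order matches ``individual_ids``, column order ``marker_ids``.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        self._index = {ind: i for i, ind in enumerate(self.individual_ids)}
        if len(self._index) != len(self.individual_ids):
            raise ValueError("duplicate individual IDs in genotype matrix")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def __contains__(self, individual: str) -> bool:
        return individual in self._index

    def row(self, individual: str) -> np.ndarray:
        """Genotype row for one individual (a view, not a copy)."""
        return self.values[self._index[individual]]

    def set_row(self, individual: str, genotypes: np.ndarray) -> None:
        self.values[self._index[individual]] = genotypes

    def is_hd(self, individual: str, min_fraction: float = 0.9) -> bool:
        """Whether an individual is genotyped at (close to) full density."""
        row = self.row(individual)
        return float(np.mean(row != MISSING)) >= min_fraction

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individual_ids), list(self.marker_ids), self.values.copy()
        )


@dataclass
class HaplotypePair:
    """Two phased allele vectors with optional parent-of-origin labels.

    ``origin1``/``origin2`` hold, per marker, the ID of the parent the
    corresponding allele was inherited from, or ``None`` when unknown.
    """

    hap1: np.ndarray
    hap2: np.ndarray
    origin1: np.ndarray | None = None
    origin2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        self.hap2 = np.asarray(self.hap2, dtype=np.int8)
        if self.hap1.shape != self.hap2.shape:
            raise ValueError("haplotype length mismatch")

    @property
    def n_markers(self) -> int:
        return self.hap1.shape[0]

    def genotypes(self) -> np.ndarray:
        """Genotype codes implied by the pair (9 where either allele is 9)."""
        geno = self.hap1 + self.hap2
        geno[(self.hap1 == MISSING) | (self.hap2 == MISSING)] = MISSING
        return geno.astype(np.int8)

    def is_homozygous(self) -> np.ndarray:
        """Boolean mask of markers where both alleles are equal and known."""
        return (self.hap1 == self.hap2) & (self.hap1 != MISSING)

    @classmethod
    def from_genotypes(cls, genotypes: np.ndarray) -> "HaplotypePair":
        """Phase the trivially phased markers of a genotype row.

        Homozygotes are phased de facto; heterozygous and missing markers
        get missing alleles.
        """
        genotypes = np.asarray(genotypes)
        hap1 = np.full(genotypes.shape, MISSING, dtype=np.int8)
        hap2 = np.full(genotypes.shape, MISSING, dtype=np.int8)
        hap1[genotypes == 0] = 0
        hap2[genotypes == 0] = 0
        hap1[genotypes == 2] = 1
        hap2[genotypes == 2] = 1
        return cls(hap1, hap2)

    def copy(self) -> "HaplotypePair":
        return HaplotypePair(
            self.hap1.copy(),
            self.hap2.copy(),
            None if self.origin1 is None else self.origin1.copy(),
            None if self.origin2 is None else self.origin2.copy(),
        )


class Pedigree:
    """Directed acyclic parent links; selfing is parent1 == parent2.

    Records are (individual, parent1, parent2) with ``None`` for unknown
    parents (founders).  The textual file convention uses 0 for unknown.
    """

    def __init__(self, records: Iterable[tuple[str, str | None, str | None]]):
        self._parents: dict[str, tuple[str | None, str | None]] = {}
        for ind, p1, p2 in records:
            if ind in self._parents:
                raise ValueError(f"duplicate pedigree record for {ind!r}")
            self._parents[ind] = (p1, p2)
        # implicit founders: named parents without their own record
        for p1, p2 in list(self._parents.values()):
            for p in (p1, p2):
                if p is not None and p not in self._parents:
                    self._parents[p] = (None, None)
        self._order = self._toposort()

    def _toposort(self) -> list[str]:
        ts: TopologicalSorter[str] = TopologicalSorter()
        for ind, (p1, p2) in self._parents.items():
            preds = [p for p in (p1, p2) if p is not None]
            ts.add(ind, *preds)
        try:
            return list(ts.static_order())
        except Exception as exc:  # cycle
            raise ValueError(f"pedigree is not acyclic: {exc}") from exc

    def __contains__(self, individual: str) -> bool:
        return individual in self._parents

    def __iter__(self):
        return iter(self._order)

    @property
    def individuals(self) -> list[str]:
        return list(self._parents)

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        return self._parents[individual]

    def is_founder(self, individual: str) -> bool:
        p1, p2 = self._parents[individual]
        return p1 is None and p2 is None

    def founders(self) -> list[str]:
        return [i for i in self._parents if self.is_founder(i)]

    def topological_order(self) -> list[str]:
        """Individuals ordered founders-first (base generation first)."""
        return list(self._order)

    def children(self, individual: str) -> list[str]:
        return [
            i
            for i, (p1, p2) in self._parents.items()
            if individual in (p1, p2)
        ]

    def cross_parents(self, individual: str) -> tuple[str, str] | None:
        """The two outcross parents of an individual's biparental family.

        Selfing chains are walked upwards until a cross between two
        distinct parents is found; founders return ``None``.  An F2 (one
        selfing of an F1 of A x B) therefore maps to (A, B).
        """
        seen = set()
        current = individual
        while True:
            if current in seen:
                raise ValueError(f"selfing loop at {current!r}")
            seen.add(current)
            p1, p2 = self._parents[current]
            if p1 is None and p2 is None:
                return None
            if p1 == p2:
                current = p1
                continue
            if p1 is None or p2 is None:
                return None
            return (p1, p2)

    def selfing_generations(self, individual: str) -> int:
        """Number of selfing records between an individual and its cross."""
        count = 0
        current = individual
        while True:
            p1, p2 = self._parents[current]
            if p1 is None and p2 is None:
                return count
            if p1 == p2:
                count += 1
                current = p1
                continue
            return count


@dataclass
class MarkerPanel:
    """High-density marker map plus the low-density subset.

    Positions are centimorgans; strictly increasing within a chromosome.
    """

    marker_ids: list[str]
    chromosomes: np.ndarray
    positions_cm: np.ndarray
    ld_marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        self.chromosomes = np.asarray(self.chromosomes)
        if len(self.marker_ids) != self.positions_cm.shape[0]:
            raise ValueError("marker/position length mismatch")
        self._index = {m: i for i, m in enumerate(self.marker_ids)}
        missing = [m for m in self.ld_marker_ids if m not in self._index]
        if missing:
            raise ValueError(f"Ld markers not in Hd panel: {missing[:5]}")
        for chrom in np.unique(self.chromosomes):
            pos = self.positions_cm[self.chromosomes == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def ld_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_markers, dtype=bool)
        for m in self.ld_marker_ids:
            mask[self._index[m]] = True
        return mask

    def marker_index(self, marker: str) -> int:
        return self._index[marker]


@dataclass
class ScenarioSpec:
    """Declarative description of one simulation scenario.

    Defaults follow the study design this package replicates: 25,000 Hd
    SNPs and 50 Ld SNPs on a single 1-Morgan chromosome, 1,000 F2 per
    cross of which 10 are genotyped at Hd, and 100 replicates.  Scaled
    runs override the sizes.
    """

    parentA_inbred: bool = True
    parentA_genotyping: str = "none"  # "none" or "ld"
    n_crosses: int = 1
    n_hd_descendants_per_cross: int = 10
    include_grandparents: bool = False
    n_f2_per_cross: int = 1000
    n_hd_snps: int = 25000
    n_ld_snps: int = 50
    n_replicates: int = 100
    seed: int = 0
    n_base_haplotypes: int = 100
    n_base_sites: int | None = None  # default: 4x the Hd panel, min 8000

    def __post_init__(self) -> None:
        if self.parentA_genotyping not in ("none", "ld"):
            raise ValueError("parentA_genotyping must be 'none' or 'ld'")
        if not 1 <= self.n_crosses <= 4:
            raise ValueError("n_crosses must be between 1 and 4")
        if self.n_hd_descendants_per_cross > self.n_f2_per_cross:
            raise ValueError("more Hd descendants than F2 per cross")
        if self.n_ld_snps > self.n_hd_snps:
            raise ValueError("Ld panel larger than Hd panel")
        if self.n_base_sites is None:
            self.n_base_sites = max(4 * self.n_hd_snps, 8000)

    @classmethod
    def numbered(cls, scenario: int, **overrides) -> "ScenarioSpec":
        """The eight canonical scenarios: 1-4 without grandparents and
        one to four crosses; 5-8 the same with Hd grandparents."""
        if not 1 <= scenario <= 8:
            raise ValueError("scenario must be 1..8")
        n_crosses = (scenario - 1) % 4 + 1
        include_gp = scenario > 4
        return cls(
            n_crosses=n_crosses, include_grandparents=include_gp, **overrides
        )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_on_error(self) -> None:
        if self.errors:
            raise ValueError("; ".join(self.errors))


def validate_inputs(
    geno: GenotypeMatrix, ped: Pedigree, panel: MarkerPanel
) -> ValidationReport:
    """Cross-check genotypes, pedigree and marker panel.

    Illegal genotype codes are fatal; individuals absent from the
    pedigree and markers absent from the panel are warnings.
    """
    report = ValidationReport()
    legal = np.isin(geno.values, [0, 1, 2, MISSING])
    if not legal.all():
        bad = np.argwhere(~legal)
        for i, j in bad[:10]:
            report.errors.append(
                f"illegal genotype code {geno.values[i, j]} for individual "
                f"{geno.individual_ids[i]!r} at marker {geno.marker_ids[j]!r}"
            )
        if len(bad) > 10:
            report.errors.append(f"... and {len(bad) - 10} more illegal codes")
    for ind in geno.individual_ids:
        if ind not in ped:
            report.warnings.append(f"individual {ind!r} not in pedigree")
    panel_markers = set(panel.marker_ids)
    for m in geno.marker_ids:
        if m not in panel_markers:
            report.warnings.append(f"marker {m!r} not in panel")
    return report
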