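"""Gene-drop simulation of biparental breeding populations.

The generator produces, on a single 1-Morgan chromosome: a set of base
haplotypes with a rare-variant-skewed allele-frequency spectrum, an inbred
base generation, the pedigree of a (possibly inbred) focal parent crossed
to one or more inbred mates, F2 descendants via one round of selfing, a
high-density marker panel with a low-density subset, and the masked
genotype matrix that mimics a realistic genotyping design (a few
descendants at high density, the rest at low density, the focal parent
ungenotyped or at low density).

Meiosis places a Poisson number of crossovers (mean = map length in
Morgans) uniformly along the chromosome, without interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    MISSING,
    GenotypeMatrix,
    HaplotypePair,
    MarkerPanel,
    Pedigree,
    ScenarioSpec,
)

CHROM_LENGTH_CM = 100.0

#: mate founder names, in cross order
MATE_NAMES = ("B", "C", "D", "E")


@dataclass
class BaseHaplotypeSet:
    """Binary base haplotypes over segregating sites on one chromosome."""

    alleles: np.ndarray  # haplotypes x sites, int8 in {0,1}
    positions_cm: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def frequencies(self) -> np.ndarray:
        """Derived-allele frequency per site in the base set."""
        return self.alleles.mean(axis=0)


def simulate_base_haplotypes(
    n_haps: int = 100,
    n_sites: int = 80000,
    rng: np.random.Generator | int | None = None,
) -> BaseHaplotypeSet:
    """Simulate base haplotypes with a neutral-equilibrium-like spectrum.

    Every site segregates: the derived-allele count k is drawn with
    probability proportional to 1/k (the neutral site-frequency spectrum),
    and the carriers are a uniform random subset of haplotypes.  Site
    positions are uniform on a 100 cM chromosome.
    """
    if n_haps < 2:
        raise ValueError("need at least two base haplotypes")
    rng = np.random.default_rng(rng)
    positions = np.sort(rng.uniform(0.0, CHROM_LENGTH_CM, size=n_sites))
    # enforce strictly increasing positions (ties are measure-zero but
    # float collisions can occur at large n_sites)
    eps = 1e-9
    for i in range(1, n_sites):
        if positions[i] <= positions[i - 1]:
            positions[i] = positions[i - 1] + eps
    k_values = np.arange(1, n_haps)
    sfs = 1.0 / k_values
    sfs /= sfs.sum()
    counts = rng.choice(k_values, size=n_sites, p=sfs)
    alleles = np.zeros((n_haps, n_sites), dtype=np.int8)
    for j in range(n_sites):
        carriers = rng.choice(n_haps, size=counts[j], replace=False)
        alleles[carriers, j] = 1
    return BaseHaplotypeSet(alleles, positions)


def meiosis(
    parent: HaplotypePair,
    positions_cm: np.ndarray,
    rng: np.random.Generator,
    length_cm: float = CHROM_LENGTH_CM,
) -> np.ndarray:
    """Sample one recombinant gamete from a fully phased parent.

    The crossover count is Poisson with mean equal to the map length in
    Morgans; breakpoints are uniform along the chromosome (no
    interference).  The starting haplotype is chosen at random.
    """
    n_xo = rng.poisson(length_cm / 100.0)
    start = rng.integers(2)
    if n_xo == 0 or np.array_equal(parent.hap1, parent.hap2):
        return (parent.hap1 if start == 0 else parent.hap2).copy()
    breaks = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    # parity of crossovers left of each site decides the source haplotype
    parity = np.searchsorted(breaks, positions_cm, side="right") % 2
    source = (start + parity) % 2
    return np.where(source == 0, parent.hap1, parent.hap2).astype(np.int8)


def select_panels(
    base: BaseHaplotypeSet,
    parent_genotypes: np.ndarray,
    n_hd: int,
    n_ld: int,
    maf_range: tuple[float, float] = (0.01, 0.50),
) -> np.ndarray:
    """Choose Hd panel site indices; the first ``n_ld`` of the returned
    structured selection are flagged as the Ld subset by the caller.

    Eligible sites segregate among the supplied parent genotype rows
    (a heterozygous parent counts as segregating) and have base-set minor
    allele frequency within ``maf_range``.  Sites are picked to be
    approximately equidistant in cM.

    Returns ``(hd_indices, ld_subindices)`` where ``ld_subindices`` index
    into ``hd_indices``.
    """
    parent_genotypes = np.atleast_2d(parent_genotypes)
    has0 = np.any(parent_genotypes <= 1, axis=0)
    has1 = np.any(parent_genotypes >= 1, axis=0)
    segregating = has0 & has1
    freq = base.frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    eligible = np.flatnonzero(
        segregating & (maf >= maf_range[0]) & (maf <= maf_range[1])
    )
    if eligible.size < n_hd:
        raise ValueError(
            f"only {eligible.size} eligible sites for a panel of {n_hd}"
        )
    hd_idx = _equidistant_subset(base.positions_cm[eligible], n_hd)
    hd_sites = eligible[hd_idx]
    ld_sub = _equidistant_subset(base.positions_cm[hd_sites], n_ld)
    return hd_sites, ld_sub


def _equidistant_subset(positions: np.ndarray, n: int) -> np.ndarray:
    """Indices of ~n approximately evenly spaced positions (greedy nearest
    to an even grid, without reuse)."""
    if n > positions.size:
        raise ValueError("subset larger than candidate set")
    if n == positions.size:
        return np.arange(n)
    targets = np.linspace(positions[0], positions[-1], n)
    chosen: list[int] = []
    last = -1
    for j, t in enumerate(targets):
        i = int(np.searchsorted(positions, t))
        candidates = [c for c in (i - 1, i, i + 1) if 0 <= c < positions.size]
        candidates = [c for c in candidates if c > last]
        if not candidates:
            candidates = [min(last + 1, positions.size - 1)]
        pick = min(candidates, key=lambda c: abs(positions[c] - t))
        # ensure room for the remaining picks
        pick = min(pick, positions.size - (n - j))
        pick = max(pick, last + 1)
        chosen.append(pick)
        last = pick
    return np.array(chosen, dtype=int)


@dataclass
class SimulatedPopulation:
    """A simulated scenario: truth plus the masked observation matrix."""

    spec: ScenarioSpec
    pedigree: Pedigree
    panel: MarkerPanel
    true_haplotypes: dict[str, HaplotypePair]
    genotypes_true: GenotypeMatrix
    genotypes_masked: GenotypeMatrix
    parent_a: str = "A"
    mates: tuple[str, ...] = ()
    hd_descendants: dict[str, list[str]] = field(default_factory=dict)
    focal_individuals: dict[str, list[str]] = field(default_factory=dict)

    def true_genotype(self, individual: str) -> np.ndarray:
        return self.true_haplotypes[individual].genotypes()


def build_scenario(
    spec: ScenarioSpec, rng: np.random.Generator | int | None = None
) -> SimulatedPopulation:
    """Simulate one replicate of a scenario.

    Pedigree: Grandparent1 x Grandparent2 -> F1; Parent A is either that
    F1 (outbred) or a fully inbred line derived from it (complete
    fixation of one recombinant F1 gamete, the in-distribution limit of
    many selfing rounds); Parent A is crossed to 1-4 inbred founder
    mates; each cross yields F2 individuals by one selfing of its own F1.

    Masking: Parent A all-missing or Ld-only; per cross the first
    ``n_hd_descendants_per_cross`` F2 keep Hd genotypes, the remaining
    (focal) F2 keep only Ld markers; mates (and grandparents when
    included) are Hd.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    base = simulate_base_haplotypes(
        spec.n_base_haplotypes, spec.n_base_sites, rng
    )
    # all candidate founders are drawn up front: the marker panel is
    # ascertained once on the genotyped founders of the whole crossing
    # program (grandparents plus every candidate mate), as a breeding
    # program would design it, independent of how many crosses a given
    # scenario uses
    founder_haps = rng.choice(
        base.n_haplotypes, size=2 + len(MATE_NAMES), replace=False
    )
    gp1_hap = base.alleles[founder_haps[0]]
    gp2_hap = base.alleles[founder_haps[1]]
    all_mate_haps = {
        name: base.alleles[founder_haps[2 + c]]
        for c, name in enumerate(MATE_NAMES)
    }
    mate_haps = {
        MATE_NAMES[c]: all_mate_haps[MATE_NAMES[c]]
        for c in range(spec.n_crosses)
    }
    mates = tuple(MATE_NAMES[: spec.n_crosses])

    # Parent A lineage at all base sites
    f1a = HaplotypePair(gp1_hap.copy(), gp2_hap.copy())
    ped_records: list[tuple[str, str | None, str | None]] = [
        ("GP1", None, None),
        ("GP2", None, None),
    ]
    if spec.parentA_inbred:
        gam = meiosis(f1a, base.positions_cm, rng)
        a_full = HaplotypePair(gam, gam.copy())
        ped_records += [("F1A", "GP1", "GP2"), ("A", "F1A", "F1A")]
    else:
        a_full = f1a
        ped_records += [("A", "GP1", "GP2")]
    for m in mates:
        ped_records.append((m, None, None))

    # marker panel: sites segregating among the genotyped founders of
    # the program (grandparents and candidate mates; segregation cannot
    # be ascertained on the ungenotyped parent), base MAF in
    # [0.01, 0.50], evenly spaced
    founder_genos = np.vstack(
        [2 * gp1_hap, 2 * gp2_hap]
        + [2 * all_mate_haps[m] for m in MATE_NAMES]
    )
    hd_sites, ld_sub = select_panels(
        base, founder_genos, spec.n_hd_snps, spec.n_ld_snps
    )
    marker_ids = [f"m{i + 1}" for i in range(spec.n_hd_snps)]
    panel = MarkerPanel(
        marker_ids,
        np.array(["1"] * spec.n_hd_snps),
        base.positions_cm[hd_sites],
        [marker_ids[i] for i in ld_sub],
    )
    pos = panel.positions_cm

    haps: dict[str, HaplotypePair] = {
        "GP1": HaplotypePair(gp1_hap[hd_sites], gp1_hap[hd_sites].copy()),
        "GP2": HaplotypePair(gp2_hap[hd_sites], gp2_hap[hd_sites].copy()),
        "A": HaplotypePair(
            a_full.hap1[hd_sites].copy(), a_full.hap2[hd_sites].copy()
        ),
    }
    if spec.parentA_inbred:
        haps["F1A"] = HaplotypePair(
            f1a.hap1[hd_sites].copy(), f1a.hap2[hd_sites].copy()
        )
    for m in mates:
        haps[m] = HaplotypePair(mate_haps[m][hd_sites], mate_haps[m][hd_sites].copy())

    hd_desc: dict[str, list[str]] = {}
    focal: dict[str, list[str]] = {}
    a_panel = haps["A"]
    for c, mate in enumerate(mates, start=1):
        mate_panel_hap = haps[mate].hap1
        hd_desc[mate] = []
        focal[mate] = []
        for i in range(spec.n_f2_per_cross):
            f1_id = f"F1_{c}_{i + 1}"
            f2_id = f"F2_{c}_{i + 1}"
            gam_a = meiosis(a_panel, pos, rng)
            f1 = HaplotypePair(gam_a, mate_panel_hap.copy())
            f2 = HaplotypePair(meiosis(f1, pos, rng), meiosis(f1, pos, rng))
            haps[f1_id] = f1
            haps[f2_id] = f2
            ped_records.append((f1_id, "A", mate))
            ped_records.append((f2_id, f1_id, f1_id))
            if i < spec.n_hd_descendants_per_cross:
                hd_desc[mate].append(f2_id)
            else:
                focal[mate].append(f2_id)

    pedigree = Pedigree(ped_records)

    genotyped: list[str] = []
    if spec.include_grandparents:
        genotyped += ["GP1", "GP2"]
    genotyped.append("A")
    genotyped += list(mates)
    for mate in mates:
        genotyped += hd_desc[mate] + focal[mate]

    true_values = np.vstack([haps[i].genotypes() for i in genotyped])
    genotypes_true = GenotypeMatrix(list(genotyped), marker_ids, true_values)

    masked = genotypes_true.copy()
    ld_mask = panel.ld_mask
    if spec.parentA_genotyping == "none":
        masked.row("A")[:] = MISSING
    else:
        row = masked.row("A")
        row[~ld_mask] = MISSING
    for mate in mates:
        for f2 in focal[mate]:
            row = masked.row(f2)
            row[~ld_mask] = MISSING

    return SimulatedPopulation(
        spec=spec,
        pedigree=pedigree,
        panel=panel,
        true_haplotypes=haps,
        genotypes_true=genotypes_true,
        genotypes_masked=masked,
        mates=mates,
        hd_descendants=hd_desc,
        focal_individuals=focal,
    )


def replicate_rngs(spec: ScenarioSpec, n: int | None = None) -> list[np.random.Generator]:
    """Independent, reproducible per-replicate generators."""
    n = spec.n_replicates if n is None else n
    seq = np.random.SeedSequence(spec.seed)
    return [np.random.default_rng(s) for s in seq.spawn(n)]
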