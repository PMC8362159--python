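"""Anchor-based phasing and imputation of a descendant of a biparental cross.

Model.  A descendant of a cross P x Q (an F1, or an F2 after one round of
selfing, or a fully fixed line) carries, at every marker, ``n`` allele
copies transmitted from parent P and ``2 - n`` from parent Q, where the
*origin dosage* ``n`` is piecewise constant along the chromosome and
changes only at crossovers.  All P-derived copies at a marker descend from
a single transmitted gamete of P (and likewise for Q), so two same-origin
copies are always equal.

Anchors.  A marker where the observed descendant genotype together with
the parents' allele sets admits exactly one origin dosage is an anchor:
for example opposing homozygous parents (0 vs 2) force the origin of every
descendant allele, and any heterozygous descendant genotype forces
``n = 1``.  Mendelian impossibilities are logged as conflicts and carry no
anchor.  Between anchors the origin dosage is extended by the
nearest-anchor rule, which places the implied crossover at the cM midpoint
between discordant anchors.

Imputation.  Each marker then receives ``n`` copies of P's transmitted
allele plus ``2 - n`` of Q's.  For an outbred parent the transmitted
haplotype (hap1 vs hap2 of that parent) is itself tracked segment-wise by
matching anchored alleles against the parent's haplotypes.  Spans whose
origin or source haplotype stays unresolved remain missing; observed
genotypes are never overwritten.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, HaplotypePair

_UNKNOWN = -1


@dataclass
class AnchorSet:
    """Anchors resolved for one descendant.

    ``indices`` are marker indices with a unique origin dosage
    ``n_from_p`` (copies inherited from parent P); ``allele_p`` /
    ``allele_q`` are the transmitted alleles where determined (9 where
    not).  ``conflicts`` lists markers whose genotype is impossible given
    the parents (no anchor is placed there).
    """

    indices: np.ndarray
    n_from_p: np.ndarray
    allele_p: np.ndarray
    allele_q: np.ndarray
    conflicts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_anchors(self) -> int:
        return self.indices.size


def _allele_availability(parent: HaplotypePair) -> tuple[np.ndarray, np.ndarray]:
    """Masks of markers where the parent may transmit allele 0 / allele 1.

    A missing haplotype allele is a wildcard: it could be either allele.
    """
    h1, h2 = parent.hap1, parent.hap2
    unknown = (h1 == MISSING) | (h2 == MISSING)
    has0 = (h1 == 0) | (h2 == 0) | unknown
    has1 = (h1 == 1) | (h2 == 1) | unknown
    return has0, has1


def assign_origin(
    child_genotypes: np.ndarray,
    parent_p: HaplotypePair,
    parent_q: HaplotypePair,
) -> AnchorSet:
    """Resolve parent-of-origin anchors for one descendant.

    Works on the full marker vector; markers with genotype 9 are ignored,
    so a low-density individual is handled by passing its row with 9 at
    unobserved markers.
    """
    g = np.asarray(child_genotypes)
    p0, p1 = _allele_availability(parent_p)
    q0, q1 = _allele_availability(parent_q)
    observed = g != MISSING

    # consistency of each origin dosage n (copies from P) with g
    c0 = np.zeros(g.shape, dtype=bool)  # n = 0: both copies from Q
    c1 = np.zeros(g.shape, dtype=bool)
    c2 = np.zeros(g.shape, dtype=bool)
    m0, m1, m2 = observed & (g == 0), observed & (g == 1), observed & (g == 2)
    c2[m0], c1[m0], c0[m0] = p0[m0], (p0 & q0)[m0], q0[m0]
    c2[m2], c1[m2], c0[m2] = p1[m2], (p1 & q1)[m2], q1[m2]
    # a heterozygote needs one copy from each side (same-origin copies
    # descend from one gamete and would be equal)
    het_pa0 = m1 & p0 & q1  # P sends 0, Q sends 1
    het_pa1 = m1 & p1 & q0
    c1[m1] = (het_pa0 | het_pa1)[m1]

    n_consistent = c0.astype(int) + c1.astype(int) + c2.astype(int)
    conflicts = np.flatnonzero(observed & (n_consistent == 0))
    anchored = observed & (n_consistent == 1)

    idx = np.flatnonzero(anchored)
    n_from_p = np.where(c2[idx], 2, np.where(c1[idx], 1, 0)).astype(np.int8)
    allele_p = np.full(idx.shape, MISSING, dtype=np.int8)
    allele_q = np.full(idx.shape, MISSING, dtype=np.int8)
    gi = g[idx]
    # homozygous descendant: both transmitted alleles equal the genotype's
    hom_allele = (gi // 2).astype(np.int8)
    hom = gi != 1
    allele_p[hom & (n_from_p >= 1)] = hom_allele[hom & (n_from_p >= 1)]
    allele_q[hom & (n_from_p <= 1)] = hom_allele[hom & (n_from_p <= 1)]
    # heterozygous descendant with unambiguous orientation
    only_pa0 = (het_pa0 & ~het_pa1)[idx]
    only_pa1 = (het_pa1 & ~het_pa0)[idx]
    allele_p[only_pa0], allele_q[only_pa0] = 0, 1
    allele_p[only_pa1], allele_q[only_pa1] = 1, 0
    return AnchorSet(idx, n_from_p, allele_p, allele_q, conflicts)


def nearest_anchor_assignment(
    anchor_positions: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """For every marker, the ordinal of the nearest anchor in cM.

    Equivalent to extending each anchor's state halfway to its
    neighbours: the switch between discordant anchors falls at the cM
    midpoint.  Ties go to the left anchor.  Returns -1 everywhere when
    there are no anchors.
    """
    if anchor_positions.size == 0:
        return np.full(positions.shape, _UNKNOWN, dtype=int)
    midpoints = (anchor_positions[:-1] + anchor_positions[1:]) / 2.0
    return np.searchsorted(midpoints, positions, side="left")


def _source_haplotype_track(
    anchors: AnchorSet,
    anchor_alleles: np.ndarray,
    parent: HaplotypePair,
    positions: np.ndarray,
) -> np.ndarray:
    """Which haplotype of ``parent`` (1 or 2) the transmitted gamete
    matches, per marker; 0 where undetermined.

    Informative anchors are those whose transmitted allele is known and
    where the parent is heterozygous with both alleles known.
    """
    h1, h2 = parent.hap1, parent.hap2
    ai = anchors.indices
    het = (h1[ai] != h2[ai]) & (h1[ai] != MISSING) & (h2[ai] != MISSING)
    known = anchor_alleles != MISSING
    informative = het & known
    track = np.zeros(positions.shape, dtype=np.int8)
    if not informative.any():
        return track
    info_idx = ai[informative]
    votes = np.where(anchor_alleles[informative] == h1[info_idx], 1, 2).astype(np.int8)
    assign = nearest_anchor_assignment(positions[info_idx], positions)
    track[:] = votes[assign]
    return track


@dataclass
class DescendantImputation:
    """Result of imputing one descendant against its cross parents."""

    genotypes: np.ndarray
    haplotypes: HaplotypePair
    anchors: AnchorSet
    origin_dosage: np.ndarray  # copies from parent P per marker, -1 unknown
    gamete_p: np.ndarray  # inferred transmitted allele of P, 9 unknown
    gamete_q: np.ndarray


def phase_focal_heterozygotes(
    child_genotypes: np.ndarray,
    anchors: AnchorSet,
    positions: np.ndarray,
) -> HaplotypePair:
    """Phase a descendant at its observed markers using anchor origins.

    Heterozygous markers between concordant anchors take that
    orientation; between discordant anchors the switch sits at the cM
    midpoint (nearest-anchor rule); markers outside all anchors inherit
    the nearest anchor.  With no anchors everything stays unphased.
    """
    g = np.asarray(child_genotypes)
    n = g.shape[0]
    hap1 = np.full(n, MISSING, dtype=np.int8)
    hap2 = np.full(n, MISSING, dtype=np.int8)
    hap1[g == 0] = 0
    hap2[g == 0] = 0
    hap1[g == 2] = 1
    hap2[g == 2] = 1
    if anchors.n_anchors == 0:
        return HaplotypePair(hap1, hap2)
    # orientation at anchors with known transmitted alleles: slot 1 is the
    # P-side copy wherever one copy comes from each parent
    oriented = (anchors.allele_p != MISSING) & (anchors.n_from_p == 1)
    if oriented.any():
        idx = anchors.indices[oriented]
        assign = nearest_anchor_assignment(positions[idx], positions)
        ap = anchors.allele_p[oriented][assign]
        het = g == 1
        hap1[het] = ap[het]
        hap2[het] = 1 - ap[het]
    return HaplotypePair(hap1, hap2)


def impute_descendant(
    child_genotypes: np.ndarray,
    parent_p: HaplotypePair,
    parent_q: HaplotypePair,
    positions: np.ndarray,
) -> DescendantImputation:
    """Impute a descendant of cross P x Q to full density.

    Runs anchor resolution, extends the origin dosage by the
    nearest-anchor rule, tracks which haplotype of each (possibly
    outbred) parent was transmitted, and copies parental alleles.
    Observed genotypes are kept verbatim.
    """
    g = np.asarray(child_genotypes)
    n = g.shape[0]
    positions = np.asarray(positions, dtype=float)
    anchors = assign_origin(g, parent_p, parent_q)

    dosage = np.full(n, _UNKNOWN, dtype=np.int8)
    no_track = np.zeros(n, dtype=np.int8)
    if anchors.n_anchors > 0:
        assign = nearest_anchor_assignment(positions[anchors.indices], positions)
        dosage = anchors.n_from_p[assign].astype(np.int8)
        track_p = _source_haplotype_track(anchors, anchors.allele_p, parent_p, positions)
        track_q = _source_haplotype_track(anchors, anchors.allele_q, parent_q, positions)
    else:
        track_p = track_q = no_track
    gam_p = _transmitted_allele(parent_p, track_p)
    gam_q = _transmitted_allele(parent_q, track_q)

    need_p = dosage >= 1
    need_q = (dosage <= 1) & (dosage != _UNKNOWN)
    imputable = (dosage != _UNKNOWN) & (
        (~need_p | (gam_p != MISSING)) & (~need_q | (gam_q != MISSING))
    )
    geno = np.full(n, MISSING, dtype=np.int8)
    dp = np.where(dosage == _UNKNOWN, 0, dosage).astype(np.int16)
    geno[imputable] = (dp * gam_p + (2 - dp) * gam_q).astype(np.int8)[imputable]
    # both parents transmit the same allele: the genotype is determined
    # even where the origin dosage is not
    forced = (gam_p != MISSING) & (gam_p == gam_q) & ~imputable
    geno[forced] = (2 * gam_p[forced]).astype(np.int8)

    hap1 = np.where(need_p, gam_p, gam_q).astype(np.int8)
    hap2 = np.where(dosage == 2, gam_p, gam_q).astype(np.int8)
    hap1[dosage == _UNKNOWN] = MISSING
    hap2[dosage == _UNKNOWN] = MISSING
    hap1[forced] = gam_p[forced]
    hap2[forced] = gam_p[forced]

    # observed genotypes are authoritative
    observed = g != MISSING
    disagree = observed & (geno != MISSING) & (geno != g)
    geno[observed] = g[observed]
    hap1[disagree] = MISSING
    hap2[disagree] = MISSING
    obs_hom0 = observed & (g == 0)
    obs_hom2 = observed & (g == 2)
    hap1[obs_hom0], hap2[obs_hom0] = 0, 0
    hap1[obs_hom2], hap2[obs_hom2] = 1, 1

    return DescendantImputation(
        genotypes=geno,
        haplotypes=HaplotypePair(hap1, hap2),
        anchors=anchors,
        origin_dosage=dosage,
        gamete_p=gam_p,
        gamete_q=gam_q,
    )


def _transmitted_allele(parent: HaplotypePair, track: np.ndarray) -> np.ndarray:
    """Allele transmitted by the parent given the source-haplotype track.

    Homozygous (or identical) parental markers need no track; at
    heterozygous markers an unresolved track leaves the allele missing.
    """
    h1, h2 = parent.hap1, parent.hap2
    allele = np.full(h1.shape, MISSING, dtype=np.int8)
    same = (h1 == h2) & (h1 != MISSING)
    allele[same] = h1[same]
    pick1 = (track == 1) & (h1 != MISSING)
    pick2 = (track == 2) & (h2 != MISSING)
    allele[pick1] = h1[pick1]
    allele[pick2] = h2[pick2]
    return allele


def attribute_gametes(
    child_genotypes: np.ndarray,
    parent_p_calls: HaplotypePair,
    parent_q: HaplotypePair,
    positions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, AnchorSet]:
    """Infer, per marker, the allele a descendant received from parent P.

    Used when reconstructing an ungenotyped parent from its descendants:
    P is only known through provisional calls.  Solves
    ``g = n * gam_p + (2 - n) * allele_q`` for the transmitted allele
    ``gam_p`` given the origin dosage ``n`` from anchor extension and the
    mate's transmitted allele.  Returns (dosage, gam_p with 9 where
    unresolved, anchors).
    """
    g = np.asarray(child_genotypes)
    positions = np.asarray(positions, dtype=float)
    anchors = assign_origin(g, parent_p_calls, parent_q)
    n = g.shape[0]
    dosage = np.full(n, _UNKNOWN, dtype=np.int8)
    gam_p = np.full(n, MISSING, dtype=np.int8)
    if anchors.n_anchors == 0:
        return dosage, gam_p, anchors

    assign = nearest_anchor_assignment(positions[anchors.indices], positions)
    dosage = anchors.n_from_p[assign].astype(np.int8)

    track_q = _source_haplotype_track(anchors, anchors.allele_q, parent_q, positions)
    allele_q = _transmitted_allele(parent_q, track_q)

    observed = g != MISSING
    g16 = g.astype(np.int16)
    with np.errstate(all="ignore"):
        # n = 2: both copies from P
        two = observed & (dosage == 2)
        gam_p[two & (g == 0)] = 0
        gam_p[two & (g == 2)] = 1
        # n = 1: subtract the mate's contribution
        one = observed & (dosage == 1) & (allele_q != MISSING)
        cand = (g16 - allele_q.astype(np.int16))
        ok = one & ((cand == 0) | (cand == 1))
        gam_p[ok] = cand[ok].astype(np.int8)
    return dosage, gam_p, anchors


def impute_focal_to_hd(
    focal_genotypes: np.ndarray,
    parent_p: HaplotypePair,
    parent_q: HaplotypePair,
    positions: np.ndarray,
) -> DescendantImputation:
    """Impute a low-density focal individual to high density.

    Thin alias of :func:`impute_descendant`; the focal row carries 9 at
    the markers outside its low-density panel.
    """
    return impute_descendant(focal_genotypes, parent_p, parent_q, positions)
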