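"""Phase and impute a parent of biparental crosses from its relatives.

Three information regimes are supported for a target parent (called
"Parent A" in the scenario fixtures):

* **ancestors only** — with no genotypes on the target, only markers where
  both of its own parents are homozygous for the same allele can be
  imputed (any selfing history may have fixed either allele elsewhere);
  with low-density genotypes on the target, those genotypes anchor a
  regular descendant imputation of the target against its parents.
* **descendants + mates** — per cross, markers where all high-density
  descendants are fixed give a homozygous call; segregating markers are
  tested for segregation distortion with a chi-square test of observed
  genotype counts against Hardy-Weinberg expectations at the observed
  allele frequency (significant distortion with a homozygous mate means
  the target is heterozygous; no distortion with a homozygous mate means
  the opposing homozygote).  Calls are combined across crosses, with
  disagreement resolved to unknown.  The called (or observed) markers
  then anchor parent-of-origin assignment of every descendant's
  haplotypes, the target-attributed gamete alleles are clustered into two
  haplotype groups at the heterozygous anchor markers, and per-locus
  majority votes within each group yield the consensus haplotype pair;
  the target's genotypes are filled as the sum of the two haplotypes.
* **both** — the two reconstructions are merged; wherever they disagree,
  even for one haplotype, both haplotype and genotype are set missing.

Observed genotypes of the target are never overwritten.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .core import MISSING, GenotypeMatrix, HaplotypePair, MarkerPanel, Pedigree
from .phasing import impute_descendant, nearest_anchor_assignment

# call codes coincide with genotype codes (9 = unknown)
CALL_HOM0, CALL_HET, CALL_HOM2, CALL_UNKNOWN = 0, 1, 2, 9

# provenance codes for ParentCallTrack
PROV_NONE = 0
PROV_ANCESTOR = 1
PROV_FREQ = 2
PROV_CHI2 = 3
PROV_LD_OBS = 4
PROV_CONSENSUS = 5

#: minimum total Hd descendants before the monomorphic rule may call a
#: homozygote (guards against chance fixation in tiny families)
MIN_DESCENDANTS_FOR_MONOMORPHIC = 4

#: weighted minority-vote fraction above which pooled (unclustered)
#: gamete votes indicate a heterozygous parent; set at the
#: likelihood-ratio boundary between a heterozygous parent (a descendant
#: is silent with probability 5/8) and a homozygous one (silent with
#: probability 1/4, pure non-transmission) under one round of selfing
SPLIT_VOTE_FRACTION = 0.45

#: minimum along-chromosome coherence (fraction of gametes keeping their
#: haplotype-group membership between neighbouring het anchors) for the
#: two-cluster consensus to be trusted; genuine clusters score near 1,
#: anchors that are not truly heterozygous split gametes at random (~0.5)
CLUSTER_COHERENCE_MIN = 0.7

#: weight of a silence-inferred vote: the probability that a descendant
#: whose genotype is fully explainable by the mate actually received a
#: mate-matching allele from the target (P(>=1 copy from the target) = 3/4
#: under one round of selfing)
SILENT_VOTE_WEIGHT = 0.75

#: a silent vote only counts within this distance (cM) of some *certain*
#: observation of the same gamete: a gamete silent over a whole
#: neighbourhood most likely received no target material there (its
#: origin-dosage segments span tens of cM) and must not vote at all
SILENT_REACH_CM = 5.0


@dataclass
class ParentCallTrack:
    """Per-marker genotype-state call for a target parent plus provenance."""

    calls: np.ndarray
    provenance: np.ndarray

    @classmethod
    def unknown(cls, n_markers: int) -> "ParentCallTrack":
        return cls(
            np.full(n_markers, CALL_UNKNOWN, dtype=np.int8),
            np.full(n_markers, PROV_NONE, dtype=np.int8),
        )

    def to_haplotype_pair(self) -> HaplotypePair:
        """Pseudo-haplotypes implied by the calls (het = one of each)."""
        n = self.calls.shape[0]
        hap1 = np.full(n, MISSING, dtype=np.int8)
        hap2 = np.full(n, MISSING, dtype=np.int8)
        hap1[self.calls == CALL_HOM0] = 0
        hap2[self.calls == CALL_HOM0] = 0
        hap1[self.calls == CALL_HOM2] = 1
        hap2[self.calls == CALL_HOM2] = 1
        hap1[self.calls == CALL_HET] = 0
        hap2[self.calls == CALL_HET] = 1
        return HaplotypePair(hap1, hap2)


@dataclass
class RelativeSet:
    """High-density relatives of a target parent, grouped by cross."""

    ancestors_hd: tuple[str, str] | None = None
    crosses: dict[str, list[str]] = field(default_factory=dict)  # mate -> descendants
    mates_hd: list[str] = field(default_factory=list)
    siblings_hd: list[str] = field(default_factory=list)

    @property
    def n_hd_descendants(self) -> int:
        return sum(len(d) for d in self.crosses.values())

    @property
    def empty(self) -> bool:
        return self.ancestors_hd is None and self.n_hd_descendants == 0


def find_targets_and_relatives(
    ped: Pedigree, geno: GenotypeMatrix, panel: MarkerPanel | None = None
) -> list[tuple[str, RelativeSet]]:
    """Identify parents needing imputation and classify their relatives.

    A target is any individual that acts as a cross parent of a genotyped
    individual (or is an ancestor of such a parent) and has missing
    high-density genotypes.  Targets are returned in pedigree
    (base-generation-first) order.  Targets without any high-density
    relatives are silently skipped by the pipeline.
    """
    candidates: set[str] = set()
    cross_of: dict[str, tuple[str, str] | None] = {}
    for ind in geno.individual_ids:
        if ind not in ped:
            continue
        cp = ped.cross_parents(ind)
        cross_of[ind] = cp
        if cp is not None:
            candidates.update(cp)
    # ancestors of candidates are candidates too (processed first)
    frontier = list(candidates)
    while frontier:
        ind = frontier.pop()
        if ind not in ped:
            continue
        cp = ped.cross_parents(ind)
        if cp is not None:
            for p in cp:
                if p not in candidates:
                    candidates.add(p)
                    frontier.append(p)

    def is_target(ind: str) -> bool:
        if ind not in geno:
            return True
        return bool(np.any(geno.row(ind) == MISSING))

    targets = [i for i in ped.topological_order() if i in candidates and is_target(i)]

    out = []
    for target in targets:
        rel = RelativeSet()
        cp = ped.cross_parents(target) if target in ped else None
        if cp is not None and all(p in geno and geno.is_hd(p) for p in cp):
            rel.ancestors_hd = cp
        target_cross = cp
        for ind in geno.individual_ids:
            if ind == target or not geno.is_hd(ind):
                continue
            ind_cp = cross_of.get(ind)
            if ind_cp is None:
                continue
            if target in ind_cp:
                mate = ind_cp[0] if ind_cp[1] == target else ind_cp[1]
                if mate == target:
                    continue  # selfing of the target itself: no mate information
                rel.crosses.setdefault(mate, []).append(ind)
                if mate in geno and geno.is_hd(mate) and mate not in rel.mates_hd:
                    rel.mates_hd.append(mate)
            elif target_cross is not None and set(ind_cp) == set(target_cross):
                rel.siblings_hd.append(ind)
        # descendant information is only usable with a high-density mate
        rel.crosses = {
            m: d for m, d in rel.crosses.items() if m in rel.mates_hd
        }
        out.append((target, rel))
    return out


def chi2_call(
    desc_counts: tuple[int, int, int],
    mate_genotype: int,
    alpha: float = 0.05,
) -> int:
    """Classify one segregating marker from descendant genotype counts.

    Observed counts (n0, n1, n2) are compared with Hardy-Weinberg
    expectations at the observed allele frequency (chi-square, 1 df: two
    free classes minus one estimated frequency).  Significant distortion
    with a homozygous mate means the parent is heterozygous; no
    distortion with a homozygous mate means the parent is the opposing
    homozygote.  A heterozygous or unknown mate, monomorphic counts, or
    an empty family give unknown.
    """
    n0, n1, n2 = desc_counts
    n = n0 + n1 + n2
    if n == 0 or mate_genotype not in (0, 2):
        return CALL_UNKNOWN
    if n1 == 0 and (n0 == 0 or n2 == 0):
        return CALL_UNKNOWN  # monomorphic: handled by the fixation rule
    p = (n1 + 2 * n2) / (2 * n)
    q = 1.0 - p
    expected = np.array([q * q * n, 2 * p * q * n, p * p * n])
    observed = np.array([n0, n1, n2], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    if stat > _chi2_dist.ppf(1.0 - alpha, 1):
        return CALL_HET
    return CALL_HOM2 if mate_genotype == 0 else CALL_HOM0


def infer_homozygous_from_descendants(
    desc_rows_by_cross: dict[str, np.ndarray],
    mate_rows: dict[str, np.ndarray],
    min_total: int = MIN_DESCENDANTS_FOR_MONOMORPHIC,
) -> ParentCallTrack:
    """Monomorphic-descendants rule: markers where every high-density
    descendant in every cross is fixed for the same homozygote, with all
    mates compatible, are called homozygous in the parent."""
    mates = list(desc_rows_by_cross)
    n_markers = next(iter(desc_rows_by_cross.values())).shape[1]
    track = ParentCallTrack.unknown(n_markers)
    total = sum(d.shape[0] for d in desc_rows_by_cross.values())
    if total < min_total:
        return track
    all_desc = np.vstack([desc_rows_by_cross[m] for m in mates])
    observed = all_desc != MISSING
    n_obs = observed.sum(axis=0)
    for allele_geno, call in ((0, CALL_HOM0), (2, CALL_HOM2)):
        fixed = (n_obs > 0) & np.all(
            ~observed | (all_desc == allele_geno), axis=0
        )
        compatible = np.ones(n_markers, dtype=bool)
        for m in mates:
            opposing = 2 - allele_geno
            compatible &= mate_rows[m] != opposing
        track.calls[fixed & compatible] = call
        track.provenance[fixed & compatible] = PROV_FREQ
    return track


def _cross_calls(
    desc_matrix: np.ndarray,
    mate_row: np.ndarray,
    alpha: float,
    allow_monomorphic: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-cross calls; returns (calls, used_chi2 mask)."""
    n_markers = desc_matrix.shape[1]
    obs = desc_matrix != MISSING
    n0 = ((desc_matrix == 0) & obs).sum(axis=0)
    n1 = ((desc_matrix == 1) & obs).sum(axis=0)
    n2 = ((desc_matrix == 2) & obs).sum(axis=0)
    n = n0 + n1 + n2
    calls = np.full(n_markers, CALL_UNKNOWN, dtype=np.int8)
    chi2_mask = np.zeros(n_markers, dtype=bool)

    mono0 = (n > 0) & (n1 == 0) & (n2 == 0)
    mono2 = (n > 0) & (n1 == 0) & (n0 == 0)
    if allow_monomorphic:
        calls[mono0 & (mate_row != 2)] = CALL_HOM0
        calls[mono2 & (mate_row != 0)] = CALL_HOM2

    seg = (n > 0) & ~mono0 & ~mono2
    mate_hom = (mate_row == 0) | (mate_row == 2)
    test = seg & mate_hom
    if test.any():
        nn = n[test].astype(float)
        p = (n1[test] + 2 * n2[test]) / (2 * nn)
        q = 1.0 - p
        e0, e1, e2 = q * q * nn, 2 * p * q * nn, p * p * nn
        stat = (
            (n0[test] - e0) ** 2 / e0
            + (n1[test] - e1) ** 2 / e1
            + (n2[test] - e2) ** 2 / e2
        )
        crit = _chi2_dist.ppf(1.0 - alpha, 1)
        sig = stat > crit
        t_idx = np.flatnonzero(test)
        calls[t_idx[sig]] = CALL_HET
        opp = np.where(mate_row[t_idx] == 0, CALL_HOM2, CALL_HOM0).astype(np.int8)
        calls[t_idx[~sig]] = opp[~sig]
        chi2_mask[t_idx] = True
    return calls, chi2_mask


def combine_cross_calls(call_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-cross calls: unanimity wins, disagreement -> unknown.

    Returns (combined calls, disagreement mask).
    """
    n_markers = call_matrix.shape[1]
    combined = np.full(n_markers, CALL_UNKNOWN, dtype=np.int8)
    disagreement = np.zeros(n_markers, dtype=bool)
    known = call_matrix != CALL_UNKNOWN
    any_known = known.any(axis=0)
    lo = np.where(known, call_matrix, 100).min(axis=0)
    hi = np.where(known, call_matrix, -100).max(axis=0)
    agree = any_known & (lo == hi)
    combined[agree] = lo[agree].astype(np.int8)
    disagreement[:] = any_known & (lo != hi)
    return combined, disagreement


@dataclass
class ConsensusResult:
    """Two layers of consensus evidence.

    ``hap1``/``hap2`` are the clustered group votes (set only when the
    two-cluster structure validated); ``pooled_value`` is the weighted
    majority of all gamete votes and ``pooled_split`` flags markers whose
    pooled vote is split enough to indicate a heterozygous parent.
    """

    hap1: np.ndarray
    hap2: np.ndarray
    het_sites: np.ndarray
    clustered: bool
    pooled_value: np.ndarray
    pooled_split: np.ndarray
    n_voting_gametes: int


def transmission_evidence(
    desc_rows: np.ndarray, mate_row: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-descendant evidence about the allele received from the target.

    With a homozygous mate (transmitting allele ``a``), any descendant
    genotype other than ``2a`` proves the target transmitted the non-mate
    allele (weight 1).  A genotype equal to ``2a`` is *silent*: it is
    fully explainable by the mate, but under one round of selfing the
    descendant still received a target gamete with probability 3/4, so
    silence is a mate-allele vote with weight 3/4.  A heterozygous or
    missing mate yields no evidence.

    Returns (alleles, weights): alleles in {0,1,9}, weights in
    {1, 0.75, 0}.
    """
    desc_rows = np.atleast_2d(desc_rows)
    mate_hom = (mate_row == 0) | (mate_row == 2)
    a_q = (mate_row // 2).astype(np.int8)  # mate's transmitted allele
    observed = desc_rows != MISSING
    usable = observed & mate_hom[None, :]
    silent = usable & (desc_rows == 2 * a_q[None, :])
    certain = usable & ~silent
    alleles = np.full(desc_rows.shape, MISSING, dtype=np.int8)
    alleles[certain] = (1 - a_q[None, :] * np.ones_like(desc_rows))[certain]
    alleles[silent] = (a_q[None, :] * np.ones_like(desc_rows))[silent]
    weights = np.zeros(desc_rows.shape, dtype=float)
    weights[certain] = 1.0
    weights[silent] = SILENT_VOTE_WEIGHT
    return alleles, weights


def _linkage_consistent_sites(
    sites: np.ndarray,
    gamete_alleles: np.ndarray,
    weights: np.ndarray,
    positions: np.ndarray,
    min_gap_cm: float = 1.0,
    min_score: float = 0.7,
    min_joint_weight: float = 3.0,
) -> np.ndarray:
    """Filter candidate het sites by agreement with a distant neighbour.

    For each site the gamete split (allele pattern, up to a global flip)
    is compared with the nearest candidate site at least ``min_gap_cm``
    away on either side; the best absolute agreement must reach
    ``min_score``.  Sites without a sufficiently informative neighbour
    are kept (no evidence against them).
    """
    z = gamete_alleles[:, sites]
    zw = weights[:, sites] * (gamete_alleles[:, sites] != MISSING)
    pos = positions[sites]
    nxt = np.searchsorted(pos, pos + min_gap_cm, side="left")
    prv = np.searchsorted(pos, pos - min_gap_cm, side="right") - 1
    keep = np.ones(sites.size, dtype=bool)
    for j in range(sites.size):
        best = None
        for j2 in (prv[j], nxt[j]):
            if j2 < 0 or j2 >= sites.size or j2 == j:
                continue
            w_pair = zw[:, j] * zw[:, j2]
            tw = float(w_pair.sum())
            if tw < min_joint_weight:
                continue
            same = float(np.sum(w_pair * (z[:, j] == z[:, j2]))) / tw
            score = max(same, 1.0 - same)  # orientation-free agreement
            best = score if best is None else max(best, score)
        if best is not None and best < min_score:
            keep[j] = False
    return sites[keep]


def consensus_haplotypes_from_descendants(
    het_sites: np.ndarray,
    gamete_alleles: np.ndarray,
    positions: np.ndarray,
    weights: np.ndarray | None = None,
) -> ConsensusResult:
    """Derive the target parent's consensus haplotype pair.

    ``gamete_alleles`` is a descendants x markers matrix of the alleles
    attributed to the target parent (9 = none), with optional per-vote
    ``weights``.  Gametes are clustered into two haplotype groups by
    agreement at the heterozygous anchor markers (chained by
    between-anchor linkage majority); the clustering is only trusted if
    gametes keep their group membership coherently along the chromosome.
    Each group then votes per locus by strict weighted majority (ties or
    empty groups give a missing allele).  The pooled vote over all
    gametes is always reported as a weaker second layer: its weighted
    majority value, and a split flag where the minority vote fraction
    exceeds the heterozygous/homozygous likelihood-ratio boundary.
    """
    n_desc, n_markers = gamete_alleles.shape
    valid = gamete_alleles != MISSING
    if weights is None:
        weights = valid.astype(float)
    hap1 = np.full(n_markers, MISSING, dtype=np.int8)
    hap2 = np.full(n_markers, MISSING, dtype=np.int8)

    certain_m = weights >= 1.0
    # a gamete's silence only counts near one of its certain
    # observations; a locally invisible gamete received no target
    # material there and is excluded from the votes
    weights = weights.copy()
    for d in range(n_desc):
        cm = np.flatnonzero(certain_m[d])
        if cm.size == 0:
            weights[d] = 0.0
            continue
        cp = positions[cm]
        right = np.searchsorted(cp, positions)
        left = np.clip(right - 1, 0, cp.size - 1)
        right = np.clip(right, 0, cp.size - 1)
        dist = np.minimum(
            np.abs(positions - cp[left]), np.abs(cp[right] - positions)
        )
        weights[d, dist > SILENT_REACH_CM] = 0.0
    silent_m = (weights > 0) & (weights < 1.0)
    valid = valid & (weights > 0)

    # pooled layer: weighted majority of all votes plus a split flag
    w0 = (weights * (gamete_alleles == 0)).sum(axis=0)
    w1 = (weights * (gamete_alleles == 1)).sum(axis=0)
    pooled_v = np.full(n_markers, MISSING, dtype=np.int8)
    pooled_v[w0 > w1] = 0
    pooled_v[w1 > w0] = 1
    tot = w0 + w1
    minority = np.minimum(w0, w1)
    pooled_split = (
        (minority >= 1.5) & (tot > 0) & (minority >= SPLIT_VOTE_FRACTION * tot)
    )

    # chain sites: the called het anchors plus split-vote candidates,
    # filtered for a het-like evidence profile (a truly heterozygous site
    # draws certain, non-mate evidence from ~3/8 of the gametes, a
    # falsely flagged homozygous site from ~3/4)
    het_sites = np.asarray(het_sites, dtype=int)
    candidate = np.zeros(n_markers, dtype=bool)
    candidate[het_sites] = True
    candidate |= pooled_split
    k = certain_m.sum(axis=0)
    s = silent_m.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = k / np.maximum(k + s, 1)
    usable = np.flatnonzero(candidate & (k >= 2) & (frac <= 0.6))

    if usable.size >= 3:
        # drop candidate sites whose gamete split does not replicate in
        # any neighbouring site >= 1 cM away: a genuine het site splits
        # the gametes by the haplotype they carry, which persists along
        # the chromosome, whereas a spurious split (silence noise at a
        # homozygous site) is independent of its surroundings
        usable = _linkage_consistent_sites(
            usable, gamete_alleles, weights, positions
        )

    cluster: np.ndarray | None = None
    if usable.size >= 2:
        # phase chain across het anchors: the weighted majority XOR of
        # gamete alleles at consecutive anchors says whether the two
        # anchors have the same or flipped haplotype orientation
        chain = np.zeros(usable.size, dtype=np.int8)
        z = gamete_alleles[:, usable]
        zw = weights[:, usable] * valid[:, usable]
        for j in range(usable.size - 1):
            w_pair = zw[:, j] * zw[:, j + 1]
            if not w_pair.any():
                chain[j + 1] = chain[j]
                continue
            flip_w = float(np.sum(w_pair * (z[:, j] != z[:, j + 1])))
            same_w = float(w_pair.sum()) - flip_w
            chain[j + 1] = chain[j] ^ (1 if flip_w > same_w else 0)
        hap1_at = chain  # allele carried by hap1 at each anchor

        # validate the clustering: genuine haplotype groups are coherent
        # along the chromosome (a gamete keeps its group between
        # neighbouring anchors, crossovers aside), whereas anchors that
        # are not truly heterozygous split the gametes at random.  Only
        # site pairs >= 1 cM apart count: descendant genotype counts are
        # blockwise constant between recombination breakpoints, so very
        # close spurious sites are trivially (and meaninglessly) coherent
        match_site = np.where(z == hap1_at[None, :], 1, 2).astype(np.int8)
        site_pos = positions[usable]
        nxt = np.searchsorted(site_pos, site_pos + 1.0, side="left")
        total_w = agree_w = 0.0
        for j in range(usable.size):
            j2 = nxt[j]
            if j2 >= usable.size:
                break
            w_pair = zw[:, j] * zw[:, j2]
            total_w += float(w_pair.sum())
            agree_w += float(
                np.sum(w_pair * (match_site[:, j] == match_site[:, j2]))
            )
        coherence = agree_w / total_w if total_w > 0 else 0.0
        if total_w >= 4.0 and coherence >= CLUSTER_COHERENCE_MIN:
            cluster = np.zeros((n_desc, n_markers), dtype=np.int8)
            site_mask = np.zeros(n_markers, dtype=bool)
            site_mask[usable] = True
            site_hap1 = np.full(n_markers, MISSING, dtype=np.int8)
            site_hap1[usable] = hap1_at

    def _group_vote(mask: np.ndarray, min_votes: int = 2) -> np.ndarray:
        """Certain (non-mate) evidence outranks silence: agreeing
        certain votes decide; a group with no certain votes but silent
        members carries the mate allele (silence from pure
        non-transmission of a whole group is (1/4)^k unlikely)."""
        c0 = (mask & certain_m & (gamete_alleles == 0)).sum(axis=0)
        c1 = (mask & certain_m & (gamete_alleles == 1)).sum(axis=0)
        s0 = (mask & silent_m & (gamete_alleles == 0)).sum(axis=0)
        s1 = (mask & silent_m & (gamete_alleles == 1)).sum(axis=0)
        out = np.full(n_markers, MISSING, dtype=np.int8)
        ct = c0 + c1
        use_c = ct >= min_votes
        out[use_c & (c0 > c1)] = 0
        out[use_c & (c1 > c0)] = 1
        use_s = (ct == 0) & (s0 + s1 >= min_votes)
        out[use_s & (s0 > s1)] = 0
        out[use_s & (s1 > s0)] = 1
        return out

    if cluster is not None:
        # progressive extension: each round, gametes are assigned to the
        # haplotype group they match at their nearest established het
        # site, group votes resolve further markers, and confidently
        # het-voted markers become new sites.  Regions whose carrier
        # ratio silences the marker-wise callers are reached wave by
        # wave from their informative flanks; a stale assignment leaves
        # a marker unvoted (conservative) rather than mis-voted.
        v1 = v2 = None
        for _ in range(300):
            sites = np.flatnonzero(site_mask)
            for d in range(n_desc):
                dv = sites[weights[d, sites] > 0]
                if dv.size == 0:
                    cluster[d] = 0
                    continue
                match = np.where(
                    gamete_alleles[d, dv] == site_hap1[dv], 1, 2
                ).astype(np.int8)
                assign = nearest_anchor_assignment(positions[dv], positions)
                cluster[d] = match[assign]
            v1 = _group_vote(cluster == 1)
            v2 = _group_vote(cluster == 2)
            new_het = (
                (v1 != MISSING) & (v2 != MISSING) & (v1 != v2) & ~site_mask
            )
            if not new_het.any():
                break
            site_mask[new_het] = True
            site_hap1[new_het] = v1[new_het]

        grouped = (v1 != MISSING) & (v2 != MISSING) & ~site_mask
        hap1[grouped] = v1[grouped]
        hap2[grouped] = v2[grouped]
        # once the site set has converged the assignments are fresh
        # everywhere, so a relaxed single-vote pass safely resolves the
        # markers the strict thresholds left open
        v1r = _group_vote(cluster == 1, min_votes=1)
        v2r = _group_vote(cluster == 2, min_votes=1)
        relaxed = (
            ~grouped & ~site_mask & (v1r != MISSING) & (v2r != MISSING)
        )
        hap1[relaxed] = v1r[relaxed]
        hap2[relaxed] = v2r[relaxed]
        hap1[site_mask] = site_hap1[site_mask]
        hap2[site_mask] = 1 - site_hap1[site_mask]

    return ConsensusResult(
        hap1, hap2, usable, cluster is not None, pooled_v, pooled_split, n_desc
    )


@dataclass
class ParentImputationResult:
    target: str
    genotypes: np.ndarray
    haplotypes: HaplotypePair
    track: ParentCallTrack
    used_ancestors: bool = False
    used_descendants: bool = False


def impute_from_ancestors(
    gp1_row: np.ndarray, gp2_row: np.ndarray
) -> ParentCallTrack:
    """Ancestor rule for an ungenotyped target: only markers where both
    of its parents are homozygous for the same allele are called (and
    phased de facto); selfing may have fixed either allele elsewhere."""
    n = gp1_row.shape[0]
    track = ParentCallTrack.unknown(n)
    both0 = (gp1_row == 0) & (gp2_row == 0)
    both2 = (gp1_row == 2) & (gp2_row == 2)
    track.calls[both0] = CALL_HOM0
    track.calls[both2] = CALL_HOM2
    track.provenance[both0 | both2] = PROV_ANCESTOR
    return track


def impute_from_descendants(
    target_observed: np.ndarray | None,
    relatives: RelativeSet,
    geno: GenotypeMatrix,
    positions: np.ndarray,
    alpha: float = 0.05,
) -> ParentImputationResult:
    """Reconstruct a parent from high-density descendants and mates.

    With no observed genotypes on the target the anchors come from the
    frequency / distortion calls; with low-density observations the
    observed genotypes are the anchors (and are never overwritten).
    """
    n_markers = geno.n_markers
    mates = list(relatives.crosses)
    track = ParentCallTrack.unknown(n_markers)

    has_ld = target_observed is not None and np.any(target_observed != MISSING)
    if has_ld:
        obs_mask = target_observed != MISSING
        track.calls[obs_mask] = target_observed[obs_mask]
        track.provenance[obs_mask] = PROV_LD_OBS
        disagreement = np.zeros(n_markers, dtype=bool)
        chi2_used = np.zeros(n_markers, dtype=bool)
    else:
        total_desc = relatives.n_hd_descendants
        allow_mono = total_desc >= MIN_DESCENDANTS_FOR_MONOMORPHIC
        call_rows, chi2_rows = [], []
        for mate in mates:
            desc = np.vstack([geno.row(d) for d in relatives.crosses[mate]])
            calls, chi2_mask = _cross_calls(
                desc, geno.row(mate), alpha, allow_mono
            )
            call_rows.append(calls)
            chi2_rows.append(chi2_mask)
        combined, disagreement = combine_cross_calls(np.vstack(call_rows))
        chi2_used = np.vstack(chi2_rows).any(axis=0)
        track.calls = combined
        track.provenance[combined != CALL_UNKNOWN] = PROV_FREQ
        track.provenance[(combined != CALL_UNKNOWN) & chi2_used] = PROV_CHI2

    # evidence about the allele each descendant received from the target
    allele_rows, weight_rows = [], []
    for mate in mates:
        desc = np.vstack([geno.row(d) for d in relatives.crosses[mate]])
        alleles, weights = transmission_evidence(desc, geno.row(mate))
        allele_rows.append(alleles)
        weight_rows.append(weights)
    if not allele_rows:
        return ParentImputationResult(
            "", track.calls.copy(), track.to_haplotype_pair(), track
        )
    gametes = np.vstack(allele_rows)
    gamete_w = np.vstack(weight_rows)

    het_sites = np.flatnonzero(track.calls == CALL_HET)
    consensus = consensus_haplotypes_from_descendants(
        het_sites, gametes, positions, gamete_w
    )

    # assemble, strongest evidence last so it wins: pooled votes (fill
    # call-unknown markers only) < direct calls < validated cluster
    # votes (override even a significant single-marker call) < observed
    # genotypes
    genotypes = np.full(n_markers, MISSING, dtype=np.int8)
    hap1 = np.full(n_markers, MISSING, dtype=np.int8)
    hap2 = np.full(n_markers, MISSING, dtype=np.int8)
    prov = track.provenance.copy()

    unknown_call = track.calls == CALL_UNKNOWN
    pooled_fill = unknown_call & consensus.pooled_split
    genotypes[pooled_fill] = CALL_HET
    maj = unknown_call & ~consensus.pooled_split & (consensus.pooled_value != MISSING)
    genotypes[maj] = (2 * consensus.pooled_value[maj]).astype(np.int8)
    hap1[maj] = consensus.pooled_value[maj]
    hap2[maj] = consensus.pooled_value[maj]
    prov[pooled_fill | maj] = PROV_CONSENSUS

    called = ~unknown_call
    genotypes[called] = track.calls[called]
    pair_fb = track.to_haplotype_pair()
    hap1[called] = pair_fb.hap1[called]
    hap2[called] = pair_fb.hap2[called]
    # an unclustered heterozygous call carries no phase information
    het_unphased = called & (track.calls == CALL_HET)
    hap1[het_unphased] = MISSING
    hap2[het_unphased] = MISSING

    grouped = (consensus.hap1 != MISSING) & (consensus.hap2 != MISSING)
    genotypes[grouped] = (consensus.hap1 + consensus.hap2)[grouped]
    hap1[grouped] = consensus.hap1[grouped]
    hap2[grouped] = consensus.hap2[grouped]
    prov[grouped & unknown_call] = PROV_CONSENSUS

    if has_ld:
        obs_mask = target_observed != MISSING
        genotypes[obs_mask] = target_observed[obs_mask]
        hom0 = obs_mask & (target_observed == 0)
        hom2 = obs_mask & (target_observed == 2)
        hap1[hom0], hap2[hom0] = 0, 0
        hap1[hom2], hap2[hom2] = 1, 1
        bad = obs_mask & (target_observed == 1) & (hap1 == hap2) & (hap1 != MISSING)
        hap1[bad] = MISSING
        hap2[bad] = MISSING

    track_out = ParentCallTrack(genotypes.copy(), prov)
    return ParentImputationResult(
        "", genotypes, HaplotypePair(hap1, hap2), track_out,
        used_descendants=True,
    )


def merge_ancestor_descendant(
    anc_pair: HaplotypePair,
    anc_geno: np.ndarray,
    desc_pair: HaplotypePair,
    desc_geno: np.ndarray,
) -> tuple[HaplotypePair, np.ndarray]:
    """Consensus of the ancestor-only and descendant-only reconstructions.

    Haplotype pairs are aligned up to a global swap (labels are
    arbitrary), then merged per haplotype per marker: agreement keeps the
    allele, one-sided information fills in, disagreement (even for one
    haplotype) sets both the haplotype allele and the genotype missing.
    """
    d1, d2 = desc_pair.hap1, desc_pair.hap2
    a1, a2 = anc_pair.hap1, anc_pair.hap2

    def _mismatch(x1, x2):
        m1 = (x1 != MISSING) & (a1 != MISSING) & (x1 != a1)
        m2 = (x2 != MISSING) & (a2 != MISSING) & (x2 != a2)
        return int(m1.sum() + m2.sum())

    if _mismatch(d2, d1) < _mismatch(d1, d2):
        d1, d2 = d2, d1

    def _merge_vec(x, y):
        out = np.where(x == MISSING, y, x).astype(np.int8)
        disagree = (x != MISSING) & (y != MISSING) & (x != y)
        out[disagree] = MISSING
        return out, disagree

    h1, dis1 = _merge_vec(a1, d1)
    h2, dis2 = _merge_vec(a2, d2)
    geno, dis_g = _merge_vec(anc_geno, desc_geno)
    blank = dis1 | dis2 | dis_g
    h1[blank] = MISSING
    h2[blank] = MISSING
    geno[blank] = MISSING
    return HaplotypePair(h1, h2), geno


def impute_parents(
    geno: GenotypeMatrix,
    ped: Pedigree,
    panel: MarkerPanel,
    alpha: float = 0.05,
) -> tuple[dict[str, ParentImputationResult], GenotypeMatrix]:
    """Impute every parent with missing genotypes, base generation first.

    Returns the per-target results and a copy of the genotype matrix with
    the imputed target rows filled in (imputed parents then serve as
    phased parents for descendant imputation).
    """
    positions = panel.positions_cm
    results: dict[str, ParentImputationResult] = {}
    out = geno.copy()
    for target, rel in find_targets_and_relatives(ped, geno, panel):
        if rel.empty:
            continue
        observed = out.row(target).copy() if target in out else None
        has_obs = observed is not None and bool(np.any(observed != MISSING))

        anc_pair = anc_geno = None
        if rel.ancestors_hd is not None:
            gp1, gp2 = rel.ancestors_hd
            if has_obs:
                imp = impute_descendant(
                    observed,
                    HaplotypePair.from_genotypes(out.row(gp1)),
                    HaplotypePair.from_genotypes(out.row(gp2)),
                    positions,
                )
                anc_pair, anc_geno = imp.haplotypes, imp.genotypes
            else:
                track = impute_from_ancestors(out.row(gp1), out.row(gp2))
                anc_pair = track.to_haplotype_pair()
                anc_geno = anc_pair.genotypes()

        desc_res = None
        if rel.n_hd_descendants > 0:
            desc_res = impute_from_descendants(
                observed if has_obs else None, rel, out, positions, alpha
            )

        if desc_res is not None and anc_pair is not None:
            pair, genotypes = merge_ancestor_descendant(
                anc_pair, anc_geno, desc_res.haplotypes, desc_res.genotypes
            )
            track = ParentCallTrack(genotypes.copy(), desc_res.track.provenance)
            result = ParentImputationResult(
                target, genotypes, pair, track,
                used_ancestors=True, used_descendants=True,
            )
        elif desc_res is not None:
            result = desc_res
            result.target = target
            result.used_descendants = True
        elif anc_pair is not None:
            track = ParentCallTrack(
                anc_geno.copy(),
                np.where(anc_geno != MISSING, PROV_ANCESTOR, PROV_NONE).astype(np.int8),
            )
            result = ParentImputationResult(
                target, anc_geno, anc_pair, track, used_ancestors=True
            )
        else:
            continue

        # observed genotypes are invariant under imputation
        if observed is not None:
            obs_mask = observed != MISSING
            result.genotypes[obs_mask] = observed[obs_mask]
        if target in out:
            out.set_row(target, result.genotypes)
        results[target] = result
    return results, out
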