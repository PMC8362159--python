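import itertools

import numpy as np
from hypothesis import given, settings, strategies as st

from bipimpute import MISSING, HaplotypePair
from bipimpute.phasing import (
    assign_origin,
    impute_descendant,
    nearest_anchor_assignment,
    phase_focal_heterozygotes,
)


def _pair(genotypes):
    return HaplotypePair.from_genotypes(np.asarray(genotypes))


class TestAssignOrigin:
    def test_opposing_homozygotes_with_homozygous_child(self):
        """Parent P genotype 0, parent Q genotype 2, child 2: both child
        haplotypes must come from Q."""
        anchors = assign_origin(np.array([2]), _pair([0]), _pair([2]))
        assert anchors.n_anchors == 1
        assert anchors.n_from_p[0] == 0
        assert anchors.allele_q[0] == 1

    def test_opposing_homozygotes_with_heterozygous_child_phase(self):
        anchors = assign_origin(np.array([1]), _pair([0]), _pair([2]))
        assert anchors.n_from_p[0] == 1
        assert anchors.allele_p[0] == 0 and anchors.allele_q[0] == 1

    def test_identical_homozygous_parents_give_no_origin(self):
        anchors = assign_origin(np.array([0]), _pair([0]), _pair([0]))
        assert anchors.n_anchors == 0 and anchors.conflicts.size == 0

    def test_impossible_genotype_is_a_conflict_not_an_anchor(self):
        anchors = assign_origin(np.array([2]), _pair([0]), _pair([0]))
        assert anchors.n_anchors == 0
        assert anchors.conflicts.tolist() == [0]

    def test_heterozygous_child_forces_one_copy_from_each_parent(self):
        # the two copies of a same-origin pair descend from one gamete,
        # so a heterozygote implies origin dosage 1 even with unknown parents
        unknown = _pair([9])
        anchors = assign_origin(np.array([1]), unknown, unknown)
        assert anchors.n_anchors == 1 and anchors.n_from_p[0] == 1


class TestNearestAnchorExtension:
    def test_switch_sits_at_the_cm_midpoint(self):
        positions = np.array([0.0, 2.0, 4.0, 5.0, 6.0, 8.0, 10.0])
        assign = nearest_anchor_assignment(np.array([0.0, 10.0]), positions)
        assert assign.tolist() == [0, 0, 0, 0, 1, 1, 1]  # tie at 5.0 -> left

    def test_single_anchor_covers_everything(self):
        positions = np.linspace(0, 100, 11)
        assign = nearest_anchor_assignment(np.array([40.0]), positions)
        assert np.all(assign == 0)


class TestPhaseFocalHeterozygotes:
    def test_concordant_flanks_phase_the_middle(self):
        geno = np.array([1, 1, 1])
        pos = np.array([0.0, 5.0, 10.0])
        anchors = assign_origin(geno, _pair([0, 9, 0]), _pair([2, 9, 2]))
        pair = phase_focal_heterozygotes(geno, anchors, pos)
        assert pair.hap1.tolist() == [0, 0, 0]
        assert pair.hap2.tolist() == [1, 1, 1]

    def test_discordant_flanks_switch_at_midpoint(self):
        geno = np.array([1, 1, 1, 1])
        pos = np.array([0.0, 3.0, 7.0, 10.0])
        # left anchor: P=0/Q=2 orients P-side to allele 0; right anchor
        # reversed, so the P-side allele flips after the midpoint (5.0)
        anchors = assign_origin(geno, _pair([0, 9, 9, 2]), _pair([2, 9, 9, 0]))
        pair = phase_focal_heterozygotes(geno, anchors, pos)
        assert pair.hap1.tolist() == [0, 0, 1, 1]

    def test_no_anchors_leave_heterozygotes_unphased(self):
        geno = np.array([1, 0, 1])
        anchors = assign_origin(geno, _pair([9, 9, 9]), _pair([9, 9, 9]))
        pair = phase_focal_heterozygotes(geno, anchors, np.array([0.0, 1.0, 2.0]))
        assert pair.hap1[0] == MISSING and pair.hap2[2] == MISSING
        assert pair.hap1[1] == 0 and pair.hap2[1] == 0  # homozygote de facto


def _oracle_min_recomb(geno, p_geno, q_geno):
    """Exhaustive minimum-crossover origin-dosage phasing.

    Enumerates every dosage path consistent with the observed genotypes
    given the parents' transmitted-allele sets, minimising the number of
    dosage changes; returns (minimal switch count, per-marker set of
    dosages seen among minimal paths).
    """
    def allele_set(g):
        return {9: {0, 1}, 0: {0}, 1: {0, 1}, 2: {1}}[g]

    def child_multisets(g):
        if g == MISSING:
            return [tuple(sorted(c)) for c in itertools.product((0, 1), repeat=2)]
        return [{0: (0, 0), 1: (0, 1), 2: (1, 1)}[g]]

    options = []
    for g, pg, qg in zip(geno, p_geno, q_geno):
        opts = set()
        for n in (0, 1, 2):
            for ap in allele_set(pg):
                for aq in allele_set(qg):
                    alleles = tuple(sorted((ap,) * n + (aq,) * (2 - n)))
                    if alleles in child_multisets(g):
                        opts.add(n)
        options.append(sorted(opts))
    best = None
    solutions = []
    for path in itertools.product(*options):
        switches = sum(abs(a - b) for a, b in zip(path, path[1:]))
        if best is None or switches < best:
            best, solutions = switches, [path]
        elif switches == best:
            solutions.append(path)
    per_marker = [set(p[i] for p in solutions) for i in range(len(geno))]
    return best, per_marker


@st.composite
def _small_instance(draw):
    n = draw(st.integers(3, 8))
    p_geno = draw(st.lists(st.sampled_from([0, 2]), min_size=n, max_size=n))
    q_geno = draw(st.lists(st.sampled_from([0, 2]), min_size=n, max_size=n))
    # child genotypes consistent with an actual transmission history
    n_from_p = [draw(st.sampled_from([0, 1, 2]))]
    for _ in range(n - 1):
        step = draw(st.sampled_from([-1, 0, 0, 0, 1]))
        n_from_p.append(min(2, max(0, n_from_p[-1] + step)))
    child = [
        npp * (pg // 2) + (2 - npp) * (qg // 2)
        for npp, pg, qg in zip(n_from_p, p_geno, q_geno)
    ]
    observed = [
        g if draw(st.booleans()) else MISSING for g in child
    ]
    return p_geno, q_geno, observed


class TestMinimumRecombinationOracle:
    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(_small_instance())
    def test_imputation_path_is_a_minimal_crossover_solution(self, instance):
        """The origin-dosage path chosen by the heuristic must achieve the
        exhaustive minimum crossover count and agree with the oracle at
        every marker where all minimal solutions coincide."""
        p_geno, q_geno, child = instance
        n = len(child)
        pos = np.linspace(0.0, 10.0 * (n - 1), n)
        res = impute_descendant(
            np.array(child, dtype=np.int8), _pair(p_geno), _pair(q_geno), pos
        )
        best, per_marker = _oracle_min_recomb(child, p_geno, q_geno)
        path = res.origin_dosage
        if np.any(path < 0):
            return  # no anchors fired: nothing to compare
        switches = int(np.abs(np.diff(path.astype(int))).sum())
        assert switches == best
        for i, allowed in enumerate(per_marker):
            if len(allowed) == 1:
                assert int(path[i]) in allowed


class TestImputeDescendant:
    def test_inbred_parents_with_anchors_impute_everything(self):
        p = _pair([0, 0, 2, 2, 0, 2])
        q = _pair([2, 2, 0, 0, 2, 0])
        pos = np.linspace(0, 100, 6)
        observed = np.array([1, 9, 1, 9, 1, 9], dtype=np.int8)
        res = impute_descendant(observed, p, q, pos)
        assert np.all(res.genotypes != MISSING)
        expected = p.genotypes() // 2 + q.genotypes() // 2
        assert np.array_equal(res.genotypes, expected.astype(np.int8))

    def test_identical_homozygous_parents_impute_without_origin(self):
        p, q = _pair([0, 0, 0]), _pair([0, 0, 0])
        res = impute_descendant(
            np.array([9, 0, 9], dtype=np.int8), p, q, np.array([0.0, 1.0, 2.0])
        )
        assert res.genotypes.tolist() == [0, 0, 0]

    def test_unknown_origin_segment_stays_missing(self):
        # single informative anchor far left; parent P heterozygous and
        # unphased on the right: those markers cannot be copied
        p = HaplotypePair(np.array([0, 0, 1], np.int8), np.array([0, 9, 9], np.int8))
        q = _pair([2, 0, 0])
        res = impute_descendant(
            np.array([1, 9, 9], dtype=np.int8), p, q, np.array([0.0, 1.0, 2.0])
        )
        assert res.genotypes[0] == 1
        assert res.genotypes[2] == MISSING

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(_small_instance())
    def test_observed_genotypes_are_never_overwritten(self, instance):
        p_geno, q_geno, child = instance
        n = len(child)
        res = impute_descendant(
            np.array(child, dtype=np.int8), _pair(p_geno), _pair(q_geno),
            np.linspace(0, 50, n),
        )
        for i, g in enumerate(child):
            if g != MISSING:
                assert res.genotypes[i] == g

    def test_imputed_alleles_trace_to_assigned_parent(self, small_scenario):
        """Copies must be verbatim parental alleles (traceability)."""
        sim = small_scenario
        pos = sim.panel.positions_cm
        a = sim.true_haplotypes["A"]
        for mate in sim.mates:
            b = sim.true_haplotypes[mate]
            for f in sim.focal_individuals[mate][:5]:
                res = impute_descendant(
                    sim.genotypes_masked.row(f), a, b, pos
                )
                for hap in (res.haplotypes.hap1, res.haplotypes.hap2):
                    known = hap != MISSING
                    parental = (
                        (hap == a.hap1) | (hap == a.hap2)
                        | (hap == b.hap1) | (hap == b.hap2)
                    )
                    assert np.all(parental[known])
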