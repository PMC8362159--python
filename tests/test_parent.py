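import numpy as np
import pytest
from scipy import stats

from bipimpute import (
    MISSING,
    GenotypeMatrix,
    HaplotypePair,
    Pedigree,
    ScenarioSpec,
    build_scenario,
)
from bipimpute.metrics import accuracy, run_replicate
from bipimpute.parent import (
    CALL_HET,
    CALL_HOM0,
    CALL_HOM2,
    CALL_UNKNOWN,
    chi2_call,
    combine_cross_calls,
    consensus_haplotypes_from_descendants,
    find_targets_and_relatives,
    impute_from_ancestors,
    impute_parents,
    infer_homozygous_from_descendants,
    merge_ancestor_descendant,
    transmission_evidence,
)
from bipimpute.sim import replicate_rngs


class TestChiSquareCall:
    def test_agrees_with_exact_multinomial_oracle_up_to_n12(self):
        """Decision must match an independent chi-square computation
        (scipy, 1 df via ddof=1) for every count vector with n <= 12."""
        alpha = 0.05
        for n in range(1, 13):
            for n0 in range(n + 1):
                for n1 in range(n + 1 - n0):
                    n2 = n - n0 - n1
                    got = chi2_call((n0, n1, n2), mate_genotype=0, alpha=alpha)
                    if n1 == 0 and (n0 == 0 or n2 == 0):
                        assert got == CALL_UNKNOWN
                        continue
                    p = (n1 + 2 * n2) / (2 * n)
                    expected = [(1 - p) ** 2 * n, 2 * p * (1 - p) * n, p * p * n]
                    _, pval = stats.chisquare([n0, n1, n2], expected, ddof=1)
                    want = CALL_HET if pval < alpha else CALL_HOM2
                    assert got == want, (n0, n1, n2)

    def test_counts_equal_to_expectation_give_opposing_homozygote(self):
        # a perfect 1:2:1 family is undistorted, so a homozygous mate
        # implies the opposing homozygote in the target parent
        assert chi2_call((3, 6, 3), mate_genotype=0) == CALL_HOM2
        assert chi2_call((3, 6, 3), mate_genotype=2) == CALL_HOM0

    def test_heterozygous_or_absent_mate_gives_unknown(self):
        assert chi2_call((1, 5, 6), mate_genotype=1) == CALL_UNKNOWN
        assert chi2_call((0, 0, 0), mate_genotype=0) == CALL_UNKNOWN


class TestMonomorphicRule:
    def test_fixed_descendants_with_compatible_mate_call_homozygote(self):
        desc = {"B": np.zeros((5, 4), dtype=np.int8)}
        mates = {"B": np.array([0, 1, 2, 9], dtype=np.int8)}
        track = infer_homozygous_from_descendants(desc, mates)
        # mate 2 is incompatible with every descendant fixed at 0
        assert track.calls.tolist() == [CALL_HOM0, CALL_HOM0, CALL_UNKNOWN, CALL_HOM0]

    def test_minimum_family_size_guard(self):
        desc = {"B": np.zeros((2, 2), dtype=np.int8)}
        mates = {"B": np.zeros(2, dtype=np.int8)}
        track = infer_homozygous_from_descendants(desc, mates)
        assert np.all(track.calls == CALL_UNKNOWN)

    def test_segregating_markers_are_not_called(self):
        desc = {"B": np.array([[0, 0], [1, 0], [2, 0]], dtype=np.int8)}
        mates = {"B": np.zeros(2, dtype=np.int8)}
        track = infer_homozygous_from_descendants(
            desc, mates, min_total=3
        )
        assert track.calls[0] == CALL_UNKNOWN
        assert track.calls[1] == CALL_HOM0


class TestAncestorRule:
    def test_only_matching_homozygous_ancestors_are_called(self):
        gp1 = np.array([0, 0, 2, 1, 9, 2], dtype=np.int8)
        gp2 = np.array([0, 2, 2, 1, 0, 9], dtype=np.int8)
        track = impute_from_ancestors(gp1, gp2)
        assert track.calls.tolist() == [
            CALL_HOM0, CALL_UNKNOWN, CALL_HOM2,
            CALL_UNKNOWN, CALL_UNKNOWN, CALL_UNKNOWN,
        ]
        pair = track.to_haplotype_pair()
        assert pair.hap1[0] == 0 and pair.hap2[0] == 0  # phased de facto


class TestCombineCrossCalls:
    def test_agreement_and_one_sided_information_pass_through(self):
        calls = np.array([
            [CALL_HOM0, CALL_HET, CALL_UNKNOWN, CALL_HOM2],
            [CALL_HOM0, CALL_UNKNOWN, CALL_UNKNOWN, CALL_HOM0],
        ], dtype=np.int8)
        combined, disagreement = combine_cross_calls(calls)
        assert combined.tolist() == [CALL_HOM0, CALL_HET, CALL_UNKNOWN, CALL_UNKNOWN]
        assert disagreement.tolist() == [False, False, False, True]


class TestConsensus:
    def test_inbred_parent_collapses_to_a_single_haplotype(self):
        # every gamete shows the same allele everywhere: the consensus
        # genotype is twice that allele, with no heterozygous calls
        alleles = np.zeros((6, 20), dtype=np.int8)
        weights = np.ones((6, 20))
        pos = np.linspace(0, 100, 20)
        cons = consensus_haplotypes_from_descendants(
            np.array([], dtype=int), alleles, pos, weights
        )
        assert not cons.clustered
        assert np.all(cons.pooled_value == 0)
        assert not cons.pooled_split.any()

    def test_tied_votes_give_missing_allele(self):
        alleles = np.array([[0], [1]], dtype=np.int8)
        weights = np.ones((2, 1))
        cons = consensus_haplotypes_from_descendants(
            np.array([], dtype=int), alleles, np.array([0.0]), weights
        )
        assert cons.pooled_value[0] == MISSING

    def test_transmission_evidence_certain_and_silent(self):
        desc = np.array([[0, 2, 1, 9]], dtype=np.int8)
        mate = np.array([0, 0, 2, 0], dtype=np.int8)
        alleles, weights = transmission_evidence(desc, mate)
        # g=0 with mate hom0 is silent (votes the mate allele, weight 3/4)
        assert alleles[0, 0] == 0 and weights[0, 0] == pytest.approx(0.75)
        # g=2 with mate hom0 proves the non-mate allele
        assert alleles[0, 1] == 1 and weights[0, 1] == 1.0
        # g=1 with mate hom2 proves allele 0 came from the target
        assert alleles[0, 2] == 0 and weights[0, 2] == 1.0
        assert weights[0, 3] == 0.0  # missing genotype: no evidence


class TestMerge:
    def test_agreement_one_sided_and_disagreement(self):
        anc = HaplotypePair(np.array([0, 9, 0], np.int8), np.array([0, 9, 0], np.int8))
        anc_geno = np.array([0, 9, 0], dtype=np.int8)
        desc = HaplotypePair(np.array([0, 1, 0], np.int8), np.array([0, 1, 1], np.int8))
        desc_geno = np.array([0, 2, 1], dtype=np.int8)
        pair, geno = merge_ancestor_descendant(anc, anc_geno, desc, desc_geno)
        assert geno[0] == 0            # agreement
        assert geno[1] == 2            # one-sided: descendants fill in
        assert geno[2] == MISSING      # disagreement, even on one haplotype
        assert pair.hap1[2] == MISSING and pair.hap2[2] == MISSING

    def test_haplotype_labels_are_aligned_up_to_global_swap(self):
        anc = HaplotypePair(np.array([0, 0, 1], np.int8), np.array([1, 1, 0], np.int8))
        swapped = HaplotypePair(np.array([1, 1, 0], np.int8), np.array([0, 0, 1], np.int8))
        pair, geno = merge_ancestor_descendant(
            anc, anc.genotypes(), swapped, swapped.genotypes()
        )
        assert np.array_equal(pair.hap1, anc.hap1)
        assert MISSING not in geno

    def test_empty_ancestor_track_passes_descendants_through(self):
        anc = HaplotypePair(np.full(3, MISSING, np.int8), np.full(3, MISSING, np.int8))
        desc = HaplotypePair(np.array([0, 1, 1], np.int8), np.array([0, 0, 1], np.int8))
        pair, geno = merge_ancestor_descendant(
            anc, anc.genotypes(), desc, desc.genotypes()
        )
        assert np.array_equal(geno, desc.genotypes())


class TestFindTargets:
    def test_scenario_targets_and_relatives(self, small_scenario):
        sim = small_scenario
        targets = dict(find_targets_and_relatives(
            sim.pedigree, sim.genotypes_masked, sim.panel
        ))
        assert "A" in targets
        rel = targets["A"]
        assert set(rel.crosses) == set(sim.mates)
        for mate in sim.mates:
            assert sorted(rel.crosses[mate]) == sorted(sim.hd_descendants[mate])
        assert sorted(rel.mates_hd) == sorted(sim.mates)
        assert rel.ancestors_hd is None  # grandparents not genotyped

    def test_fully_genotyped_parent_is_not_a_target(self):
        geno = GenotypeMatrix(
            ["P", "Q", "K"], ["m1", "m2"],
            np.array([[0, 2], [2, 0], [1, 9]]),
        )
        ped = Pedigree([("K", "P", "Q")])
        targets = [t for t, _ in find_targets_and_relatives(geno=geno, ped=ped)]
        assert targets == []

    def test_grandparents_reported_as_ancestors_when_genotyped(self):
        spec = ScenarioSpec(
            parentA_inbred=False, parentA_genotyping="ld",
            include_grandparents=True, n_hd_snps=300, n_ld_snps=15,
            n_f2_per_cross=12, n_hd_descendants_per_cross=4,
            n_base_sites=3000, seed=23,
        )
        sim = build_scenario(spec)
        targets = dict(find_targets_and_relatives(
            sim.pedigree, sim.genotypes_masked, sim.panel
        ))
        assert targets["A"].ancestors_hd == ("GP1", "GP2")


class TestPipelineInvariants:
    def test_observed_genotypes_invariant_under_imputation(self, small_scenario):
        sim = small_scenario
        results, imputed = impute_parents(
            sim.genotypes_masked, sim.pedigree, sim.panel
        )
        observed = sim.genotypes_masked.row("A")
        out = results["A"].genotypes
        mask = observed != MISSING
        assert np.array_equal(out[mask], observed[mask])
        assert np.array_equal(imputed.row("A"), out)

    def test_haplotype_sum_matches_genotype_where_phased(self, small_scenario):
        sim = small_scenario
        results, _ = impute_parents(sim.genotypes_masked, sim.pedigree, sim.panel)
        res = results["A"]
        pair_geno = res.haplotypes.genotypes()
        known = pair_geno != MISSING
        assert np.array_equal(pair_geno[known], res.genotypes[known])

    def test_parent_reconstruction_is_accurate_on_small_scenario(self, small_scenario):
        sim = small_scenario
        results, _ = impute_parents(sim.genotypes_masked, sim.pedigree, sim.panel)
        acc = accuracy(sim.true_genotype("A"), results["A"].genotypes)
        assert acc > 0.9


class TestQualitativeOrderings:
    """An inbred parent is easier than an outbred one, and low-density
    genotypes help over none; asserted over matched seeded replicates."""

    @staticmethod
    def _mean_accuracy(inbred, genotyping, reps=6):
        spec = ScenarioSpec(
            parentA_inbred=inbred, parentA_genotyping=genotyping,
            n_crosses=1, n_hd_snps=800, n_ld_snps=30, n_f2_per_cross=60,
            n_hd_descendants_per_cross=10, n_replicates=reps,
            n_base_sites=6000, seed=314,
        )
        return np.mean([
            run_replicate(spec, rng)["parent_accuracy"]
            for rng in replicate_rngs(spec)
        ])

    def test_inbred_at_least_outbred_and_ld_at_least_none(self):
        acc = {
            (i, g): self._mean_accuracy(i, g)
            for i in (True, False) for g in ("none", "ld")
        }
        tol = 0.01  # replicate noise guard on matched seeds
        assert acc[(True, "none")] >= acc[(False, "none")] - tol
        assert acc[(True, "ld")] >= acc[(False, "ld")] - tol
        assert acc[(True, "ld")] >= acc[(True, "none")] - tol
        assert acc[(False, "ld")] >= acc[(False, "none")] - tol
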