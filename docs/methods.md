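# Methods

## Scope and model

`bipimpute` targets biparental plant-breeding populations: two parents
(P and Q) crossed to make F1, selfed once to make an F2 family, with a
marker panel on a single chromosome measured in centimorgans. The
central object is the **origin dosage** of a descendant: at every
marker its two allele copies consist of *n* ∈ {0, 1, 2} copies of one
transmitted gamete of P and *2 − n* of one gamete of Q. This holds
exactly for an F1 (n ≡ 1), for an F2 (both copies descend from the
single F1, which carried one gamete from each side), and for a fully
fixed (doubled-gamete) line; it does not hold beyond one round of
selfing, where multiple gametes of the same grandparent can coexist.
That is the model's main structural assumption, and matches the designs
the package simulates. A corollary used throughout: two same-origin
copies are always equal, so any heterozygous descendant genotype forces
n = 1 regardless of parental genotypes.

Genotypes are 0/1/2 with 9 missing; haplotype alleles 0/1 with 9
missing; a genotype equals the sum of its two haplotype alleles
wherever both are known.

## Descendant imputation (anchors and dosage extension)

`assign_origin` enumerates, per observed marker, which dosages are
consistent with the child's genotype given each parent's transmittable
allele set (a missing parental allele is a wildcard). Markers with
exactly one consistent dosage are anchors; markers with none are
Mendelian conflicts and are logged but carry no anchor (robustness to
genotyping error rather than hard failure). Between anchors the dosage
is extended by nearest anchor in cM, which places the implied crossover
at the midpoint between discordant anchors — the simplest rule
consistent with single-generation recombination, and verified against
an exhaustive minimum-crossover oracle on small instances. For an
outbred parent, which of its two haplotypes the transmitted gamete
matches is tracked the same way from anchors where the transmitted
allele is known and the parent is heterozygous. Spans with unresolved
origin or source haplotype stay missing; observed genotypes are never
overwritten. Markers where both parents transmit the same allele are
imputed even with unknown dosage.

## Parent reconstruction from descendants and mates

Marker-wise calls come first. Per cross: families where every Hd
descendant is fixed for one homozygote give a homozygous call when the
mate is compatible (guarded by a minimum of 4 Hd descendants in total;
with fewer, chance fixation of a heterozygous parent's allele,
probability (5/8)^k per family, is too likely). Segregating markers
with a homozygous mate are tested for segregation distortion: observed
genotype counts against Hardy–Weinberg proportions at the observed
allele frequency, χ² with 1 df (three classes, one estimated
frequency), α = 0.05. Significant distortion ⇒ heterozygous parent; no
distortion ⇒ the opposing homozygote to the mate. α and the df are
conventional choices; exact enumeration of all count vectors (the test
suite's oracle) puts the type-I rate at 0.043 and the power against a
heterozygous parent at 0.133 for 10 descendants — the test is a weak
detector at family sizes breeders use, which is why the consensus step
below carries most of the weight. The opposing-homozygote default is
applied only to segregating markers (monomorphic families are handled
by the fixation rule; as printed, the rule would otherwise miscall
markers where parent and mate share a homozygote). Calls are combined
across crosses; any disagreement becomes unknown.

**Transmission evidence.** With a homozygous mate transmitting allele
*a*, a descendant genotype other than 2·*a* proves the parent
transmitted the non-mate allele (weight 1); a genotype equal to 2·*a*
is *silent* — explainable by the mate alone — and is read as a
mate-allele vote with weight 3/4, the probability the descendant
received any parental copy at all under one selfing. Silence is only
evidence near substance: a silent vote counts only within 5 cM of some
certain observation of the same gamete, because a gamete silent over a
whole neighbourhood most likely received no parental material there
(origin-dosage segments span tens of cM), and treating such gametes as
carriers of a phantom mate-like haplotype was the largest error source
in development. Heterozygous or missing mates yield no evidence.

**Consensus haplotypes.** Candidate heterozygous sites (χ²-called hets
plus markers whose pooled vote is split beyond the het/hom
likelihood-ratio boundary of 0.45) are filtered twice: for a het-like
evidence profile (certain-vote fraction ≤ 0.6; a truly heterozygous
site draws certain evidence from ~3/8 of gametes, a false one from
~3/4) and for linkage consistency with a neighbouring site ≥ 1 cM away
(descendant counts are blockwise constant between recombination
breakpoints, so nearer sites are trivially correlated). A phase chain
orients the surviving sites by weighted between-site XOR majorities,
and the clustering is accepted only if gametes keep their group
membership coherently between sites ≥ 1 cM apart (threshold 0.7;
genuine clusters score near 1, spurious splits near 0.5). Group votes
are lexicographic: ≥ 2 agreeing certain votes decide; a group with no
certain votes and ≥ 2 silent members carries the mate allele. Markers
voted heterozygous become new chain sites and the assignment is
recomputed — a progressive wavefront that reaches chromosome arms whose
carrier ratio silences the marker-wise callers; a stale assignment
leaves a marker unvoted rather than mis-voted. After convergence a
relaxed single-vote pass resolves what the strict thresholds left open.

**Assembly**, weakest to strongest: pooled votes fill only call-unknown
markers; direct calls next; validated cluster votes override even a
significant single-marker call (a false-positive distortion call is
outvoted by the descendants' haplotypes); observed genotypes always
win. Where clustering is rejected — the typical inbred parent, whose
candidate het sites are pure noise — the marker-wise calls stand, and
the reconstruction accuracy is limited by the χ² type-I rate (~0.98 for
a single cross), which is also what the validation study reports.
Ties and empty groups give missing alleles: the package prefers missing
over guessing throughout, consistent with its merge rule.

## Ancestors, and merging two reconstructions

For an ungenotyped target, only markers where both of its parents are
homozygous for the same allele are imputable from ancestors (any
selfing history may have fixed either allele elsewhere); these are
phased de facto. With Ld genotypes on the target, the target is simply
imputed as a descendant of its parents using its observed markers as
anchors. When both ancestor- and descendant-based reconstructions
exist, their haplotype pairs are aligned up to a global label swap
(minimum mismatches) and merged per haplotype per marker: agreement
keeps the allele, one-sided information fills in, disagreement — even
on one haplotype — blanks both haplotype and genotype. This trades
yield for accuracy, which is exactly the behaviour the validation study
reports for the grandparent scenarios.

## Simulator

The built-in generator supplies every input. Base haplotypes are binary
site matrices with derived-allele counts drawn from the neutral
site-frequency spectrum (P(k) ∝ 1/k) and positions uniform on a 100 cM
chromosome; every site segregates. It reproduces the statistical
contract that matters downstream (segregating-site density, rare-skewed
spectrum, MAF-filtered panel on a 1 M map) and deliberately omits
linkage disequilibrium and demographic history; an external coalescent
engine can be substituted where realistic LD matters. Founders are
inbred (one base haplotype doubled). Meiosis places a Poisson number of
crossovers (mean = map length in Morgans) uniformly, without
interference. A fully inbred parent is produced by analytic fixation —
doubling one recombinant F1 gamete — which matches the distribution of
many selfing rounds (residual heterozygosity (1/2)^n) at a fraction of
the cost. Each F2 descends from its own selfed F1.

The marker panel is ascertained once per program on the genotyped
founders (both grandparents and every candidate mate): sites must
segregate among them and have base minor-allele frequency in
[0.01, 0.50], then are picked approximately equidistant in cM; the Ld
panel is an equidistant subset of the Hd panel. Ascertaining on the
(possibly ungenotyped) target parent instead would be impossible in
practice and would condition the panel on the target's heterozygosity.

Masking mirrors the genotyping design: the target parent all-missing or
Ld-only; the first *k* F2 per cross at Hd; remaining (focal) F2 at Ld;
mates, and grandparents when included, at Hd.

What passing simulation-based tests does and does not show: the
simulator has no genotyping error, no missing data outside the design,
no segregation-distortion loci, and independent sites in the base
population — so the results certify the inheritance logic and the
calling rules under clean Mendelian transmission, not robustness to
assay error or to real-genome LD structure.

## Validation study and problem sizes

The desk-scale study (`bipimpute.study`) replicates the published
validation design at 2,000 Hd SNPs, 50 Ld SNPs, 200 F2 per cross and
60 replicates per condition (100 for the focal-F2 comparison, whose
replicate distribution is heavy-tailed: the gap is dominated by
occasionally hard-to-impute parents). These sizes keep every condition
within a few seconds per replicate while leaving all reported effects
large against their standard errors; accuracy in this design is
governed by family size and map length, not marker count, so reducing
the panel from 25,000 to 2,000 markers changes sampling noise, not the
expected values.

Known limitations surfaced by the study: chromosome arms where one
parental haplotype reaches few or no Hd descendants are irrecoverable
from descendant information (the consensus falls back to homozygous
calls there), which is the dominant error source for an outbred
ungenotyped parent and the main driver of between-replicate variance;
and a single cross with 10 descendants leaves the distortion test's
false positives (~4%) uncorrected when the parent is inbred, bounding
that condition near 0.98. Multi-cross and 50-descendant conditions are
reconstructed essentially without error, slightly above the published
values of the original implementation.

## Numerical and degenerate-input choices

Ties in any vote give missing. A pedigree selfing loop or cycle is an
error; founders may appear implicitly. Accuracy is undefined (NaN) for
constant vectors and computed only over imputed markers; yield of an
empty panel is an error. All randomness flows through
`numpy.random.Generator`; scenario replicates use `SeedSequence.spawn`
so every replicate and every condition has an independent,
reproducible stream.
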