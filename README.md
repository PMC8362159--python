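# bipimpute

Heuristic phasing and genotype imputation for biparental plant breeding
populations — including reconstruction of a parent that was never
genotyped, or genotyped only at low density, from its high-density
relatives.

## The problem

Genomic selection wants high-density (Hd) SNP genotypes on thousands of
selection candidates per cycle. The affordable design genotypes the few
parents at Hd and the many descendants at low density (Ld), then imputes
the descendants to Hd through the pedigree. That design breaks when a
parent has no usable Hd genotypes — lost samples, poor DNA, pedigree
errors, or a parent simply not deemed worth genotyping. `bipimpute`
closes the gap: it reconstructs the missing parent's phased Hd genotypes
from whatever relatives are available (its own parents, its mates, its
Hd-genotyped descendants) and then imputes the Ld descendants against
the reconstructed parent.

Genotypes are coded 0/1/2 (0 and 2 the homozygotes), 9 missing. All
positions are centimorgans on a single chromosome; multiple chromosomes
are independent runs.

## The method

For a descendant of a cross P × Q (an F2 after one round of selfing, in
the canonical design), the two allele copies at any marker consist of
*n* copies of a single transmitted gamete of P and *2 − n* of Q, with
the origin dosage *n* piecewise constant along the chromosome. Markers
where the observed genotype admits exactly one *n* (e.g. opposing
homozygous parents, or any heterozygous descendant genotype) are
**anchors**; between anchors the dosage extends by the nearest-anchor
rule, placing implied crossovers at cM midpoints, and parental alleles
are copied accordingly.

A parent with missing genotypes is reconstructed in three steps:

1. **Homozygote inference.** Per cross, markers where all Hd descendants
   are fixed for one homozygote (with a compatible mate) are called
   homozygous in the parent.
2. **Segregation-distortion test.** At segregating markers with a
   homozygous mate, observed descendant genotype counts are tested
   (χ², 1 df, α = 0.05) against Hardy–Weinberg expectations at the
   observed allele frequency. Significant distortion ⇒ the parent is
   heterozygous; no distortion ⇒ the opposing homozygote to the mate.
   Calls are combined across crosses; disagreement ⇒ unknown.
3. **Descendant consensus.** Each descendant's genotypes are decomposed
   into mate-explained and parent-proven alleles; the parent-attributed
   gamete alleles are clustered into two haplotype groups at the
   heterozygous anchor markers (validated by along-chromosome linkage
   coherence and extended progressively), and per-locus majority votes
   within each group yield the parent's consensus haplotype pair. The
   genotype is the sum of the two haplotypes.

If the parent's own parents are Hd-genotyped, an independent
ancestor-based reconstruction is derived (only same-homozygote markers
when the parent is ungenotyped; a full anchor-based imputation when it
has Ld genotypes), and the two reconstructions are merged: wherever they
disagree, even for one haplotype, both haplotype and genotype are set
missing. Observed genotypes are never overwritten.

Accuracy is the Pearson correlation between true and imputed genotype
codes over imputed markers; yield is the fraction of Hd markers imputed.

## Worked example

```bash
python examples/02_impute_missing_parent.py
```

```
parent A: accuracy (true-vs-imputed correlation) = 0.9952
parent A: yield (fraction of Hd markers imputed)  = 1.0000
call provenance: 1135 frequency/fixation, 865 distortion test, 0 descendant consensus
miscalled markers: 18 of 2000
```

A fully inbred, fully ungenotyped parent of a single cross is
reconstructed from one Hd mate and ten Hd F2 descendants at 2,000
markers: every marker receives a call (yield 1.0), the correlation with
the simulation truth is 0.995, and the 18 miscalls are markers whose
family counts looked distorted by chance. The other examples cover
simulation (`01`), the ancestor/descendant merge with its yield cost
(`03`), and the cost of imputing focal F2 against the reconstructed
rather than the true parent (`04`).

The same workflow is available from the shell:

```bash
bipimpute simulate --scenario 1 --outbred --parent-genotyping none \
    --hd-snps 2000 --f2 200 --seed 1 --out sim/
bipimpute impute --geno sim/geno.txt --ped sim/pedigree.txt \
    --map sim/map.txt --ld-markers sim/ld_markers.txt --out imp/
bipimpute evaluate --truth sim/true_geno.txt \
    --imputed imp/offspring_geno.txt --out report.tsv
```

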