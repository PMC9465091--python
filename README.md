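# abdmap

Locating a novel, fully penetrant autosomal recessive lethal variant from a
handful of sequenced animals — typically a few affected offspring (cases)
and their obligate-carrier parents (controls) — by combining four
independent lines of evidence from one multi-sample VCF:

1. **Genotype criteria (GCR).** At the causal site every case must be
   homozygous for one allele and every carrier heterozygous for it. With
   *n* cases and *m* carriers the pattern arises by chance at a single
   site with probability 1/3ⁿ·1/3ᵐ (each animal lands in one of three
   genotype states), so a file of *S* sites yields *S*/3ⁿ⁺ᵐ expected
   chance matches — e.g. 14 million sites and 15 animals leave ≈ 0.98
   expected sites. Genotypes are gated on GQ > 12 and DP > 11.
2. **Autozygosity-by-difference (ABD).** The new variant sits on a long
   founder haplotype, so cases are homozygous across a long run of
   homozygosity (ROH) around it. The ABD score at each SNV is the mean
   ROH length (Kb) spanning that position in cases minus the same mean in
   controls; breed-wide ROH present in both groups cancel. Genome-wide
   significance comes from permuting the case/control labels and pooling
   the permuted per-site scores: the empirical (1−α) quantile of the pool
   is the threshold.
3. **Novelty (NoRS).** The variant is new, so its site carries no dbSNP
   rs accession; the strict form also requires every sequenced animal to
   carry at least one alternate allele.
4. **Annotation impact.** A lethal is likely disruptive: sites whose VEP
   `CSQ` annotation reaches impact HIGH (splice acceptor/donor, stop
   gained, frameshift, …).

A site surviving the intersection of all four sets is the prime
candidate. The package also ships a gene-drop simulator that generates
VCFs with exactly this structure (plus ground truth for validation) and
an exact Fisher–Freeman–Halton r×c test for confirmation genotyping
tables.

## Worked example

Simulate a nine-animal design (3 affected calves, 6 carrier parents, one
splice-acceptor lethal planted at 10 Mb on chromosome 2 of a 3 × 20 Mb
genome) and run the full pipeline:

```sh
abdmap simulate --seed 8 --out-dir demo/sim
abdmap run --vcf demo/sim/sim.vcf --phenotypes demo/sim/phenotypes.tsv \
           --out-dir demo/out --seed 8
```

which prints

```
Methods intersected: GCR, ABD, NoRS9, SIFT
1 site(s) present in all 4 sets:
  2:10000000  [ABD=4200.2 Kb]
```

— the single site matching the genotype criteria, scoring above the
permutation threshold, lacking an rsID while all nine animals carry the
alternate allele, and annotated HIGH, is the planted causal position;
its ABD score (the case-minus-control mean ROH length at the site) is
printed alongside. The exit status is 0 only when the candidate is
unique. Intermediate TSVs (per-chromosome GCR table with observed and
expected counts, the ABD track with empirical p-values, significant
regions, the overlap matrix with optional region-restricted counts in
parentheses) are written to the output directory.

The same stages are available individually (`abdmap gcr`, `abdmap abd`,
`abdmap filters nors9`, `abdmap filters impact`, `abdmap intersect`),
and the library surface mirrors them; the ABD core is a model/results
pair:

```python
from abdmap import AutozygosityDifferenceModel, read_phenotypes

phen = read_phenotypes("demo/sim/phenotypes.tsv")
results = AutozygosityDifferenceModel.from_vcf("demo/sim/sim.vcf", phen).fit(
    n_perm=100, alpha=0.01, seed=8
)
print(results.summary())          # threshold, max score, regions
results.plot_manhattan(out="abd.png")
```

A confirmation genotyping table is tested exactly:

```sh
abdmap stats --table "4,2,7;0,6,0;13,9,0"
# two-sided p = 1.854e-05
```

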