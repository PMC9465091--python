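# Methods

This note documents the statistical model behind each stage, the
parameters that matter, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Genotype criteria (GCR)

At a fully penetrant autosomal recessive site sequenced in affected
offspring and their obligate-carrier parents, Mendelian segregation
forces a fixed pattern: all cases homozygous for one allele, all
carriers heterozygous and carrying it. The scanner tests this pattern
per VCF record after gating every phenotyped genotype on per-genotype
quality: **GQ > 12 and DP > 11, strict inequalities** (GQ is used rather
than site QUAL because the gate applies to individual genotypes). A
record failing the gate in any one animal is skipped entirely.

Under the null that each animal independently falls in one of the three
genotype states with probability 1/3, the pattern occurs at one site
with probability 1/3ⁿ⁺ᵐ, so `expected_gcr_count(S, n, m) = S / 3^(n+m)`.
Two pattern modes are exposed:

* `either_homozygote` (default) — cases may be homozygous for either
  allele, the verbatim textual criterion. Under the uniform null this
  mode matches `2·S/3^(n+m)` sites in expectation.
* `alt_only` — the case allele must be non-reference; this is the single
  pattern whose expectation is exactly `S/3^(n+m)`.

The discrepancy between the textual criterion and the single-pattern
probability model is deliberate and surfaced rather than resolved: both
modes are implemented and the expectation table always reports
`S/3^(n+m)`. Table display uses nearest-integer rounding with halves
away from zero (so 8.51 → 9 and 32.37 → 32).

`min_animals_for_unique_site(S)` returns the smallest k with
`S/3^k ≤ 1`, computed in exact integer arithmetic (no floating log).

## Runs of homozygosity and the ABD score

Biallelic SNVs only enter the zygosity matrix; indels and multiallelic
records are counted and skipped. **Missing genotypes are recoded to
homozygous reference** under the default policy; the alternative
`missing_policy="break"` treats a missing call as a run breaker, which
avoids inflating ROH in low-coverage samples — the default is the
convention this method was defined with, the alternative is offered
because the default is anti-conservative under heavy missingness.

A run of homozygosity is a maximal stretch of consecutive homozygous
calls (either homozygote class) on one chromosome of one individual;
heterozygous calls and chromosome ends terminate runs. Run length is
the **inclusive span** `(end_pos − start_pos + 1)/1000` Kb — endpoints
are the outermost homozygous sites, not midpoints to flanking
heterozygotes; the inclusive span is simple, deterministic and
oracle-checkable. An isolated homozygous site is a 1 bp (0.001 Kb) run.

The ABD score at a site is the unweighted arithmetic mean of the
containing-run length over cases minus the same mean over controls
(heterozygous sites contribute 0). Because per-sample run lengths do not
depend on the phenotype labels, the per-sample × per-site length matrix
is computed once and every (re)labelling is a row average — this is what
makes the permutation test cheap.

### Permutation threshold

Each permutation reallocates animals to case/control groups uniformly at
random without replacement, preserving group sizes, and recomputes the
full track. All permuted per-site scores are **pooled** and the
empirical (1−α) quantile of the pool (quantile method "higher", so the
threshold is an attained score) is the genome-wide threshold. Pooling is
the only way 100 permutations can support α = 0.01: per-site use of 100
replicates bottoms out at p = 1/101. Per-site empirical p-values are
computed against the same pool as `(1 + #{pooled ≥ observed})/(1 +
pool size)`, which is never zero. With 9 animals in a 3/6 split there
are only C(9,3) = 84 distinct labelings, so requesting more permutations
than labelings samples labelings with replacement (logged).

Significant regions are maximal consecutive stretches of sites with
score ≥ threshold; the reported span is `end − start + 1` bp. In the
fully degenerate case (all animals genetically identical) every pooled
score equals the observed one, the threshold equals the constant score
and all p-values are 1 — significance should then be judged by the
p-values, not the ≥-threshold set, which is why both are emitted.

### Hard filtering

Before ROH analysis on real data, sites can be hard-filtered on per-site
metrics (default variables: QUAL and INFO/DP). `fixed` mode applies
configured min/max bounds; `auto_2sd` estimates each variable's mean and
standard deviation over all sites in a first pass and keeps sites within
mean ± 2 s.d. in a second. A zero standard deviation filters nothing,
and a record lacking a metric is not filtered on it (absence of evidence
is not treated as a violation). The pipeline default is **no hard
filter**: the simulator's QUAL/DP fields carry no miscall signal, so
2 s.d. trimming there would only discard 5% of sites at random —
including, occasionally, the causal one. On real callsets the filter
should be enabled.

## Novelty and impact filters

rs-number syntax is `^rs\d+$`, case-insensitive, applied to each
semicolon-separated ID token; any matching token disqualifies the site.
The strict all-alt form additionally requires every sample's genotype to
contain at least one non-reference allele; missing alleles do **not**
count as alt (a missing call is not evidence of the variant).

VEP `CSQ` entries are parsed using the field layout declared in the
`##INFO=<ID=CSQ,...>` header. The IMPACT sub-field is used verbatim when
present; otherwise impact is looked up from the bundled Ensembl
consequence-term → impact table (`data/consequence_impact.tsv`), with
unknown terms degrading to MODIFIER under a logged warning. A site's
impact is the maximum over its transcript annotations
(HIGH > MODERATE > LOW > MODIFIER) — one HIGH transcript suffices. SIFT
numeric scores are parsed and reported when present but never
recomputed; "high impact" is an annotation-category judgement, and both
the HIGH record count and the deduplicated position count are reported
because several transcripts can annotate one position.

## Intersection

Site sets are keyed by `(chrom, pos)` — linking on position, not
alleles (an allele-aware key can be attached when constructing a set).
The overlap report computes the full intersection lattice for 2–4 sets:
per-set sizes on the diagonal, the pairwise lower triangle, then each
combination of leading sets against the remaining ones. An optional
region restriction recomputes every count on region-restricted sets and
prints it in parentheses. The final candidates are the intersection of
all sets; with no four-way survivor the report names the largest
(k−1)-way survivors instead.

## Exact r×c test

The Fisher–Freeman–Halton p-value is the probability-mass criterion:
enumerate every table with the observed margins (nested recursion over
free cells with margin-feasibility pruning; the last row and column are
forced), score each by its multivariate hypergeometric probability
computed from log-factorials, and sum the probabilities of tables whose
probability is ≤ that of the observed table, with a relative tolerance
of 1e-7 on the comparison to absorb floating error. No mid-p
correction. The enumeration asserts internally that all table
probabilities sum to 1 within 1e-8. All-zero rows and columns are
removed first (they are inert). Tables with total count above 200 are
refused and routed to the Monte-Carlo fallback, which samples
margin-preserving tables row-by-row from the multivariate hypergeometric
distribution and reports the (k+1)/(B+1)-corrected estimate with its
standard error.

For the 3×3 status-by-genotype confirmation table
[[4,2,7],[0,6,0],[13,9,0]] the exact two-sided p is 1.853795e-05
(cross-checked against R's `fisher.test` during development; the suite
cross-checks the 2×2 special case exhaustively against scipy).

## Gene-drop simulator

The generator produces the statistical structure the pipeline assumes,
not a demographic model. Design:

* **Sites.** Per chromosome, positions are uniform without replacement
  at `snv_density` per Mb; allele frequencies are i.i.d. uniform on
  [`maf_min`, `maf_max`]; background sites are in linkage equilibrium.
  A coalescent would add realism (LD, frequency spectrum) but none of
  the pipeline stages depend on it.
* **Founder segment.** The causal variant is new: its alternate allele
  exists only on one fixed founder haplotype pattern spanning
  ±`ibd_halflength_bp` around `causal_pos`, tagged with an ancestry
  label. Each carrier lineage starts from a founder carrying that
  segment (identical inside the window, independent background outside
  — representing the many unmodelled generations since the mutation
  arose) and descends through `pedigree_depth` carrier × non-carrier
  meioses with Poisson crossovers at `recombination_rate` cM/Mb.
* **Samples.** The `n_controls` carrier parents are the lineage feet;
  cases are bred from carrier pairs and accepted when homozygous for the
  causal ancestry (bounded retries, then an error advising a different
  seed or deeper pedigree). The emitted truth records each case's
  realised homozygous-IBD interval from the ancestry arrays, so tests
  can check recovery against exact boundaries.
* **Noise.** Genotype error flips homozygote ↔ heterozygote
  symmetrically at `genotype_error_rate`; calls drop to `./.` at
  `missing_rate`; GQ ~ N(`gq_mean`, `gq_sd`) clipped to [0, 99],
  DP ~ Poisson(`dp_mean`).

Defaults are a desk-scale version of a nine-animal deep-WGS design:
3 cases / 6 carrier parents; 3 chromosomes × 20 Mb at 25 SNVs/Mb
(≈ 1,500 sites — small enough that a full pipeline run takes well under
a second, large enough that every stage has realistic inputs); causal
site mid-chromosome-2 on a ±3 Mb founder segment; 1 cM/Mb; pedigree
depth 3; error and missing rates 0.001 each (typical of ~30× short-read
joint calling); GQ 60 ± 15, DP ~ Poisson(30); 90% of background sites
carry fake rsIDs; all sites carry CSQ annotations (1% background HIGH,
10% MODERATE, remainder MODIFIER; the causal site is
`splice_acceptor_variant`/HIGH). `null_simulate` reuses the machinery
with unrelated founders, no causal site and random labels; its
`uniform_thirds` mode draws each genotype uniformly from the three
zygosity states with perfect quality — the exact null of the GCR
expectation formula.

What passing tests on these data do **not** show: behaviour under real
LD structure, allele-frequency spectra, relatedness between "unrelated"
founders, batch effects in coverage/quality, or ROH length
distributions of real breeds. The generator is a correctness instrument
for the pipeline's logic, not a population-genetic forecast.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the full pipeline on
20 replicate gene drops (~1,500 sites × 9 samples, 100 permutations
each) plus five null replicates — a scale chosen so the complete
validation executes in seconds while keeping every stage's statistics
meaningful. All randomness flows from explicit seeds
(`numpy.random.default_rng`); the simulator is byte-deterministic under
its config seed, and the acceptance script fans one command-line seed
out to all stages.

## Known limitations

* The ABD threshold rule (pooled quantile) is one defensible choice;
  per-permutation maxima would give a more conservative family-wise
  bound. The pooled rule is documented, seeded and tested for
  super-uniformity under the null.
* Missing→hom-ref recoding inflates ROH in low-coverage samples; use
  `missing_policy="break"` when missingness is non-trivial.
* The GCR scanner requires every phenotyped genotype to pass the
  quality gate; a single low-quality call at the causal site hides it
  (at the simulator's default noise this costs ~2–3% of runs, the main
  reason pipeline recovery sits near rather than at 100%).
* Sites are intersected by position only; two different alleles at one
  position are conflated unless allele-aware keys are used.
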