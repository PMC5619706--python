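# Methods

`pathepi` implements pathway-level discovery of genetic interactions from
case-control genotype data.  This note records the statistical model, the
numerical choices, what the synthetic cohorts do and do not emulate, and
the known limitations.

## The discovery model

Individual SNP-SNP epistasis tests are hopelessly underpowered at GWAS
scale, but model-organism screens show that genetic interactions cluster:
pairs of compensating pathways accumulate many weak interactions between
them.  The pipeline therefore scores *pathway blocks* rather than SNP
pairs, in five stages:

1. **Quality control.**  Samples with > 5% missing genotypes are removed,
   then SNPs with > 5% missingness, minor-allele frequency below 5%, or an
   exact Hardy-Weinberg test p < 1e-6 (computed in controls only, the
   standard GWAS convention, since a true disease association distorts
   case genotype proportions).  All thresholds are strict inequalities.
   The pass is iterated to a fixed point so that the filter is idempotent
   (removing a badly-missing SNP changes the surviving samples' missing
   fractions).  Relatedness is removed at PI_HAT > 0.2 using the
   method-of-moments identity-by-state estimator; of a flagged pair the
   member with more missing data is dropped (ties: lexicographically
   larger sample id, for determinism).  LD is pruned with a greedy
   sliding-window r² filter (defaults r² > 0.1, window 50 SNPs, step 5;
   the defaults are package choices, not literature values).  Ancestry
   adjustment against an external reference panel is out of scope;
   case-control balancing is a seeded uniform downsample of the larger
   class.

2. **SNP-pathway mapping.**  A SNP maps to every gene overlapping a
   ±50 kb window centered on it (closed intervals), and to the pathways of
   those genes.  Pathways keep between 10 and 300 genes *with mapped
   SNPs* and between 10 and 300 SNPs; both filters describe the matrix
   actually analyzed, after pruning.

3. **SNP-pair scoring.**  Under a disease-model coding (recessive:
   carrier iff homozygous minor; dominant: carrier iff ≥ 1 minor allele),
   the risk evidence for a pair is the hypergeometric upper tail (one-
   sided Fisher p) for case enrichment among *joint* carriers, accepted
   only when strictly smaller than both single-SNP marginal tails — a
   marginality screen that encodes interaction beyond main effects.
   Score = −log10 of the joint tail, else 0.  Protective scores swap the
   roles of cases and controls.  The combined model takes the per-pair
   maximum over the four coding assignments {RR, RD, DR, DD}; the
   additive model uses a 2-df χ² of collapsed joint dosage (total minor
   alleles binned 0–1 / 2 / 3–4) with an analogous marginal screen and a
   direction sign from the high-dosage class.  Missing genotypes are
   pairwise-complete.  Numerics: with no missing data the case/control
   totals are constant, so all tails come from one precomputed
   (n_joint × n_case) survival table (log-gamma pmf + reverse cumsum) —
   O(1) per pair; mathematically tied tails are screened out, protected
   against float noise by a 1e-9 relative epsilon (distinct exact tails
   at these sample sizes differ far more).

4. **Lenient network and block tests.**  Each side (risk/protective)
   keeps the top ⌊δ·total-pairs⌋ positive-scoring pairs (ties broken
   lexicographically by SNP id), so the network density ρ is controlled
   directly.  Blocks are tested for edge-density enrichment:
   * χ²_global — 2×2 Pearson χ² of block density against the rest of the
     network, one-tailed (0 unless enriched);
   * χ²_local — one-sample χ² of the block's edge count against the
     *larger* of the two pathways' marginal densities (conservative: the
     enrichment must beat the stronger marginal);
   * p_perm — the block's density rank among SNP-label permutations,
     (1 + #{null ≥ obs}) / (1 + n_perm).
   BPM universes exclude SNPs shared by both pathways; WPM excludes
   self-pairs; PATH (hub) pathways use a one-tailed Mann-Whitney test of
   member versus non-member degrees (exact when both groups ≤ 12 and
   untied, else normal approximation with tie correction; all-tied input
   returns p = 0.5), plus a p_perm on mean member degree.
   One label shuffle permutes every pathway's membership simultaneously,
   so a block's null depends only on its membership sizes; nulls are
   cached per size signature and shared across same-sized blocks, which
   is what makes thousands of permutations cheap.  Because all blocks of
   one size share one null sample, and because of the add-one rule,
   p_perm is discrete and slightly conservative; calibration is checked
   with the randomized-PIT form, which is exactly uniform on the
   attainable grid under exchangeability.

5. **FDR and reporting.**  Results are ranked by (p_perm, χ²_global,
   χ²_local) lexicographically.  The whole pipeline is re-run under
   case-control label permutations (default 10), and FDR(k) = mean
   permuted count at least as significant as k over the real count,
   clipped to [0, 1] and made monotone non-decreasing down the ranking.
   Risk/protective directions and the three block kinds are separate
   hypothesis families.  Discoveries at FDR ≤ 0.25 are reported, then
   collapsed by redundancy: blocks whose pathway SNP sets match with
   Jaccard ≥ 0.25 on both sides (directly or swapped) are grouped by
   transitive closure, keeping the smallest-p_perm representative.

   A known property, verified empirically here: with only 10 label
   permutations, the *top* result of a family has roughly a 1-in-4 chance
   under a pure null of seeing ≤ 2 permuted exceedances and hence an FDR
   estimate ≤ 0.25.  Across six families this makes spurious
   single-block "discoveries" in roughly half of null runs.  This is
   inherent to few-permutation empirical FDR, not a calibration bug (the
   real run's family-top rank is uniform among the permuted tops); treat
   an isolated top-block FDR ≈ 0 with caution, or raise the number of
   sample permutations.

## Multi-cohort analyses

*Replication* re-evaluates discovered blocks in an independent cohort
with the discovery cohort's model and density (1,000 label permutations),
flagging each of the three statistics at nominal p ≤ 0.05; χ² statistics
convert to p-values through the 1-df survival function.  Set-level
replication resamples equally many candidate blocks (without
replacement, 1,000+ draws) to get a fold change and empirical p for the
replicated count.  *Consensus* keeps blocks with all statistics nominally
significant in ≥ 2 cohorts and ranks them by the geometric mean of the
supporting cohorts' p_perm values (p_perm only; using all three
statistics is exposed via the per-cohort tables but not default); its
significance comes from 100 re-runs of the consensus procedure on
randomly chosen sample-permutation runs of each cohort.  Cohorts are
harmonized by SNP-id intersection; allele flips and strand resolution are
real-data concerns out of scope for synthetic universes.  *Focal
restriction* reruns discovery with the BPM family limited to pairs
involving one pathway — 2(n−1) directed hypotheses instead of n(n−1) —
with FDR estimated inside the reduced family; this is the power-gain
mechanism for interrogating a hub pathway.  *Gene-degree fold enrichment*
is each SNP's degree/(M−1) over the network density ρ, averaged per gene
(expectation 1 under a uniform random network).

## The synthetic cohorts

`generate_pathway_universe` lays out non-overlapping genes (20 kb bodies,
120 kb gaps — more than twice the mapping window, so pathway SNP sets are
exact) and samples gene sets without replacement.  `generate_cohort`
places SNPs evenly inside gene bodies, draws genotypes in Hardy-Weinberg
proportions at per-SNP MAFs uniform on (0.05, 0.45) by default, and
assigns disease through a logistic model whose only non-baseline terms
are planted joint-carrier indicators: for each causal SNP pair carried
jointly under its coding, ±effect_log_odds.  The liability is centered at
the analytic mean planted load, so the baseline prevalence is independent
of effect strength and marginal SNP associations arise *only* through the
planted interactions.  Cases and controls are rejection-sampled to exact
quotas.  Optional LD blocks append noisy copies of template SNPs
(per-entry flip probability) to exercise pruning; missingness is uniform.

What this does not emulate: realistic human LD structure, allele-
frequency spectra, population stratification, genotyping batch effects,
imputation artifacts, covariates or X-chromosome inheritance.  Passing
tests show the machinery is correct and calibrated under clean
assumptions, not that the method's power on real cohorts matches these
numbers.

## Demo scale and defaults

The suite and the acceptance script run at a desk scale chosen to keep a
full multi-run study in minutes on one core: 25 pathways × 10 genes × 2
SNPs/gene (500 SNPs), 300 cases / 300 controls, dominant model, δ = 0.05,
2,000 SNP-label permutations, 10 case-control permutations.  The planted
reference effect is a dominant-coded risk BPM between two 20-SNP pathways
with a ln 3 joint log-odds bump on 30% of cross pairs; the weak focal
variant uses ln 1.2 on 5% of cross pairs, sized to sit below genome-wide
FDR ≤ 0.25 but within reach of the restricted family.  Defaults
elsewhere: pilot model selection scores candidates by
#{p_perm ≤ 0.05} − 0.05·#blocks with precedence combined > dominant >
recessive > additive, then smaller δ; redundancy Jaccard threshold 0.25;
consensus resamples 100; replication permutations 1,000.

## Limitations

* The permutation FDR instability at the family top (above) is the main
  caveat for small permutation counts.
* The additive model is exercised by property tests only; the pilot never
  selected it in our planted scenarios, mirroring how dominance-coded
  carrier statistics dominate this design.
* `estimate_relatedness` uses the uncorrected method-of-moments
  estimator; at a few hundred SNPs its null spread reaches ±0.25, so
  PI_HAT thresholds near 0.2 will flag occasional unrelated pairs (the
  removal rule keeps this harmless for balanced designs).
* Redundancy filtering is quadratic in the number of discoveries; fine at
  desk scale, would need blocking for 10^5-discovery tables.
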