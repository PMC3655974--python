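# Methods

## The statistic

The unit of inference is a gene set (an interactome); the data are
per-SNP association p-values.  The observed statistic is the number of
set members that survive a three-step reduction of SNP-level signal to
independent gene-level signal:

1. **Window mapping.** SNP *s* is assigned to gene *g* iff they share a
   chromosome and `start(g) − W ≤ pos(s) ≤ end(g) + W`, with
   `W = 20 000 bp` and both bounds inclusive.  A SNP may serve several
   genes; no nearest-gene arbitration is applied, because index-SNP
   selection and LD pruning downstream prevent one physical signal from
   being counted twice.  Genes with no assigned SNP are *unmappable*
   and excluded from the universe.
2. **Index SNP.** Per gene, the assigned SNP with the smallest p-value;
   ties broken by smaller position, then lexicographic rsid, so results
   are order-independent.  A gene is *significant* when its index p is
   strictly below P-CUT ("stronger than" the cutoff; an index p exactly
   equal to P-CUT does not qualify).
3. **LD pruning.** Significant genes are visited in ascending index-p
   order; a gene is retained iff its index SNP is independent of every
   already-retained index SNP.  Independence: different chromosome, or
   |Δpos| > 1 000 000 bp (strict), or r² ≤ 0.2 (r² exactly 0.2 counts
   as independent; an absent LD pair is r² = 0, the diagonal is 1).
   Greedy strongest-first is the standard clumping convention and is
   deterministic; dropped genes are logged against the retained gene
   that absorbed them.

## The bootstrap null

Per set, B random gene sets of the same *mappable* size are drawn
without replacement from the mappable-gene universe and scored against
the same pruned list.  Sampling uses exponential keys
(`Exp(1)/w_i`, smallest k kept — Efraimidis–Spirakis), which draws
sequentially with probability proportional to the remaining weights;
`w_i` is gene *i*'s assigned-SNP count when size weighting is on
(default) and 1 otherwise.  The weighting gives random sets the same
structural advantage that long or SNP-dense genes enjoy under the
null.  Replicate sizes are matched on mappable members rather than raw
set size because unmappable members can never contribute a count (in
the synthetic genome the two coincide).

The empirical p-value is the add-one estimator
`(1 + #{b : n_b ≥ n_obs}) / (B + 1)`: never exactly 0, at most 1
(printed as `1.0000` in the results table).

**Study-wide level.**  For each of S simulated studies, each set elects
one replicate count as pseudo-observed and scores it against B counts
resampled with replacement from its remaining replicates; the study
records how many sets reach `alpha_category` (default 0.05).  The mean
over studies is the expected number of significant sets per null
study, and the add-one tail of the real count against that null
distribution is the study-wide p.  In the original gene-category
formulation the categories are GO terms; here each interactome is one
category.

**Masked/unmasked arms.**  When a region mask is supplied (the analogue
of the extended-MHC exclusion), the whole analysis runs twice: once on
all SNPs, once with SNPs inside any mask interval removed (bounds
inclusive; genes are kept and simply lose the masked signal).  Both
arms consume identical seed streams derived from the master seed with
`SeedSequence.spawn`, so a mask that removes no SNP reproduces the
unmasked p-values exactly and the two arms stay comparable in general.

**Sensitivity scan.**  The sets significant at the primary cutoff are
re-analysed at P-CUT ∈ {0.005, 0.03, 0.05} (all sets via a flag),
emitted as a long-format table.

## Synthetic data

The generator emulates the features the analysis is sensitive to, at
desk scale:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 300 | genes over `n_chromosomes` = 5 |
| `gene_length_median`, `gene_length_sigma` | 20 kb, 0.8 | log-normal lengths |
| `snp_density_per_kb` | 1.0 | genic Poisson SNP density |
| `intergenic_density_factor` | 0.2 | intergenic density multiplier |
| `mean_intergenic_gap` | 60 kb | exponential gaps (min 2 kb) |
| `ld_block_size`, `ld_rho` | 10, 0.7 | copula blocks; LD table reports r² = ρ² |
| `spiked_set_size`, `spike_fraction`, `alt_p_shape` | 30, 0.3, 0.1 | planted signal |
| `n_sets` | 13 | one spiked + 12 null sets |

Null p-values come from a Gaussian copula: within each block of
`ld_block_size` consecutive SNPs the latent normals share pairwise
correlation ρ (`z = √ρ·z₀ + √(1−ρ)·ε`), and `p = Φ(z)` makes every
marginal exactly uniform.  Spiking replaces the p-values of all
index-eligible SNPs (window SNPs) of a random `spike_fraction` of the
spiked set's members with Beta(a, 1) draws, the standard spiked-uniform
alternative.  Gaps are wide enough that a fraction of intergenic SNPs
maps to no gene; the lower intergenic density mirrors gene-centric
genotyping arrays.  The evidence generator plants the four curation
cases (two sources / one source one method / one source two methods /
indirect only) with known outcomes.

Not emulated: realistic human LD maps, allele frequencies,
genotype-level effects, population structure, overlapping genes, and
real interactome membership.  Passing tests therefore demonstrate the
*mechanics* and the *statistical contracts* of the pipeline, not its
behaviour on real GWAS panels.

## Numerical and design choices

* Coordinates are 1-based inclusive internally; BED input is converted
  on read.  Chromosome labels are normalized (`chr6` → `6`).
* Invalid input rows are dropped with warnings and a count (mirroring
  upstream QC filtering); `strict` upgrades them to errors.
* Curation compares source identifiers after trimming and methods
  case-insensitively after trimming; `unknown` interaction class is
  treated as non-direct; symbols are emitted uppercase.  The
  two-source/two-method rule is applied per human gene per evidence
  table (one table per environmental factor).
* Generated p-values are clipped to `[1e-300, 1]` so they stay inside
  the valid domain (0, 1].
* All randomness flows from one master seed through
  `numpy.random.SeedSequence`; results tables are byte-identical across
  runs with the same seed.

## Known limitations

Two properties of the desk-scale study conditions are worth stating
plainly, because the test suite measures them honestly:

* **Tie conservatism.**  The count statistic is a small integer, so its
  null distribution has 4–6% point masses near the 95th percentile.
  The add-one estimator with `≥`-tie counting is therefore
  conservative: across 500 synthetic null studies the rejection rate of
  a weighted random 30-gene set at p ≤ 0.05 is ≈ 0.026–0.028, at the
  lower edge of the 99% binomial band around 0.05.  This is inherent to
  count-valued permutation statistics at these set sizes; randomized
  tie-breaking or mid-p estimators would remove it but change the
  estimator.
* **Power at the default spike.**  With 1 SNP/kb, a ±20 kb window and
  P-CUT 0.05, roughly 45% of genes carry a significant index SNP under
  the null, so the ~9 truly-associated genes of the default spiked set
  (30 × 0.3) sit within about one standard deviation of the weighted
  replicate counts: detection at p < 0.05 succeeds in only a few
  percent of runs.  Detection becomes reliable as the spike fraction
  grows (the README demo uses 0.8) or the null per-gene significance
  rate falls (sparser SNP panels or tighter P-CUT).
* **Partial size-bias correction.**  SNP-count-proportional sampling
  corrects the ordinary size bias of random sets but cannot fully
  calibrate a set composed *exclusively* of the densest-decile genes,
  because P(gene significant) saturates in SNP count while sampling
  weight is linear in it; unweighted sampling is strictly worse, which
  the suite asserts directionally.
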