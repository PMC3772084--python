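# Methods

## The founding model

A selfing species originates at time `T_f` generations ago when `k`
chromosomes ("founding haplotypes") are sampled from a large outcrossing
ancestral population; the new population immediately recovers to an
effective size of `N_R` chromosomes and thereafter evolves with a pairwise
coalescence rate of `1/N_R` per generation.  All times are expressed in
units of `N_R` generations, so the scaled founding time is
`T = T_f / N_R` and a pair of lineages coalesces at rate 1.

Backwards in time, sampled selfer lineages (one haplotype per predominantly
selfing individual — selfing makes individuals effectively haploid at the
coalescent scale) follow a Kingman coalescent truncated at `T`; the
survivors are assigned independently and uniformly to the `k` founders, and
lineages sharing a founder merge instantly (a founder is a single
chromosome, so within-founder coalescence at the founding generation is
negligible on this scale).  Founder lineages then join the ancestral
population, where they and the outcrossing relative's lineages coalesce at
the ancestral rate.  The ancestral population size is assumed constant and
equal to the extant outcrosser's, so outcrosser diversity is the proxy for
ancestral diversity.  Introgression after the founding is assumed absent
(and is checked empirically with Patterson's D).

Mutation is infinite-sites with per-site population rates
`theta_selfer = 2 N_R μ` inside the selfing phase and `theta_anc = 2 N_A μ`
in the ancestral/outcrosser phase.

## Synthetic data: what it emulates and what it does not

The simulator (`founderscan.synthetic_data`) draws each genomic window as an
unlinked, internally non-recombining locus under exactly the model above,
then renders diploid genotypes: selfers are homozygous from a single
haplotype except inside injected allozygous tracts, where a second,
independently simulated haplotype creates genuine heterozygotes; spurious
heterozygotes and missingness are added per genotype.  Defaults are
calibrated to the statistical structure of a young selfer/outcrosser pair:

| parameter | default | meaning / rationale |
|---|---|---|
| `theta_anc` | 0.0186 | ancestral diversity per site: expected outcrosser synonymous diversity ≈ 1.86% |
| `theta_selfer` | 0.0005 | `2 N_R μ`; puts within-founder diversity near 0.04%, an order of magnitude below genome-wide selfer diversity (≈ 0.4% at the other defaults) |
| `k_founders`, `t_scaled` | 100, 1.7 | the fitted regime: many founders, scaled time 1.7 |
| `n_selfer`, `n_outcrosser` | 6, 5 | panel sizes, selfers split into two geographic groups |
| `err_het` | 0.0013 | spurious heterozygote rate per homozygous selfer genotype (≈ 0.13% of sites heterozygous in autozygous regions) |
| `miss_rate` | 0.05 | per-genotype missingness |
| `f_allo`, `allo_mean_len` | 0.07, 200 kb | ≈ 7% of a selfer genome in allozygous tracts, exponential lengths |
| `n_windows`, `window_bp` | 500, 5 kb | genome size and founder-block scale (see below) |
| `frac_fourfold` | 0.4 | fraction of sites labelled 4-fold degenerate (the rest 0-fold); the simulator is neutral, so the labels only exercise the class bookkeeping |
| `cm_per_mb` | 2.7 | linear genetic map (≈ 339 cM over ≈ 125 Mb) |

The reference allele is the ancestral one for 70% of sites
(`P_REF_DERIVED = 0.3`), so polarization by annotation and by outcrosser
major allele are genuinely different code paths.

**Geometry matters.**  Because windows are unlinked, the window length *is*
the founder-block scale: founder state changes abruptly at window
boundaries, which is faster than any real genome.  Consequences: (i)
pairwise runs can bridge short single-founder stretches; (ii) estimators
that select regions by their own evidence see stronger finite-block
selection bias than they would on real data, where founder blocks span
hundreds of kb.  Tests therefore use 5 kb windows where breakpoint density
is the point (painting accuracy), 1 kb windows where tract length must
dwarf block length (allozygosity recovery — the regime in which the
original by-eye annotation operated), and 50 kb windows for the diversity
partition, the long-tract regime.  Noise and demography parameters stay at
their defaults throughout; these choices are about which geometry makes a
given comparison meaningful, and they are fixed here, not tuned per run.
What passing tests show is that each stage recovers the truth of this
idealized mosaic; they do not certify behaviour under real recombination
gradients, gene conversion, alignment artifacts or reference bias.

## Allozygosity segmentation

A two-state chain (autozygous / allozygous) over *informative sites*
(non-singleton polymorphic sites across the full two-species panel;
singletons are error-enriched) with Bernoulli heterozygosity emissions.
Initialization: `p_allo` from the sample-averaged pairwise selfer
difference per informative site; `p_auto` from the heterozygosity rate
outside tract-like 50-site windows (density ≥ p_allo/2), falling back to
the genome-wide rate when that trim removes every heterozygote (which it
does whenever `p_allo < 2/50`); transitions from a prior mean tract length
(200 kb) and prior allozygous fraction (5%).  One round of
expectation–maximization refines all four parameters; the Viterbi path
yields tracts, with boundaries at midpoints between flanking informative
sites.

A genuine tract is internally mosaic: where its two haplotypes happen to
carry the same founding haplotype the heterozygosity signal vanishes, so
the decoded path fragments into the signal-dense stretches.  Calls closer
than `merge_gap_bp` (50 kb) are therefore merged — the algorithmic
equivalent of the visual smoothing a human annotator applies to
cumulative-heterozygosity plots.  With default noise this recovers fixed
200-kb tracts at ≈ 95% base-level Jaccard, and the called-tract
heterozygosity matches between-sample diversity within a few percent (the
internal consistency check).  Small-sample caveat: with only tens of
realized heterozygotes genome-wide the (p_auto, transitions) pair is weakly
identified and the fitted `p_auto` can undershoot.

## Painting

Stages, with defaults in `PaintingConfig`:

1. **Jointly polymorphic sites** segregate in the selfer panel and have
   outcrosser minor-allele count ≥ `min_gr_count` (1).  For a pair, a site
   where both are homozygous is SAME or DIFFERENT; heterozygous or missing
   genotypes are ignored.
2. **Pairwise runs.**  Maximal runs of SAME with ≥ 4 supporting sites
   spanning ≥ 1.5 kb, and of DIFFERENT with ≥ 2 supporting sites, become
   intervals spanning exactly their first to last supporting site — no
   extrapolation into flanking regions.  Two independent joint differences
   cannot arise within one founding haplotype absent recurrent mutation or
   error, which motivates the DIFFERENT threshold.
   A DIFFERENT run is additionally split where the gap between consecutive
   supporting sites contains ≥ `diff_split_gr_snps` (10)
   outcrosser-polymorphic sites at which the pair is identical over
   ≥ `diff_split_bp` (2 kb): chance agreement at one ancestral SNP is
   common, identity across many consecutive ones contradicts distinct
   founders, so a DIFFERENT call must not bridge such a stretch.  (The
   symmetric stretches are deliberately *not* painted SAME: two distinct
   founders that coalesced just before the founding are sequence-identical
   over long ranges, and painting them shared would blur the founder
   partition.)
3. **Invariant regions** — maximal stretches (≥ 25 kb, ≥ 10 outcrosser
   SNPs) where every selfer with data is identical at
   outcrosser-polymorphic sites — assign all samples one shared founder.
   These thresholds are exposed in config; the sensitivity sweep
   (`founderscan sweep`) reports the headline statistics across them.
4. **Network assembly.**  The genome is cut at every interval boundary;
   within each window, samples group by transitive closure of SAME
   relations, a DIFFERENT edge inside a closed group marks the whole group
   ambiguous, samples with no informative relation are ambiguous whenever
   any relation exists, windows with none stay unassigned, and allozygous
   samples are excluded.  Founder indices are assigned in first-sample
   order; the partition is order-invariant by construction (and tested by
   permutation).
5. **Pairwise sharing** (the Fig-2-style fractions) uses the *direct*
   pairwise evidence plus invariant regions, not equality of network
   indices: two network groups that merely lack a connecting relation are
   not known to be different founders.

On error-free synthetic data at `k=10, T=1.7` (5 kb windows), ≥ 95% of
assigned bases carry the correct same/different status against simulator
truth; with default noise and masking first, ≥ 90%.  The residual errors
are dominated by founder pairs whose lineages coalesced shortly before the
founding — distinct by label, near-identical in sequence, and intrinsically
indistinguishable to any sequence-based method.

6. **Trio scan.**  For every selfer trio, windows of 20 outcrosser-common
   sites (minor count ≥ 2), advanced one site at a time, are candidates for
   a >2-founder region when all three pairwise diversities are
   ≥ 0.01/bp over the window span while at least one trio member matches a
   non-trio sample at ≤ 0.001/bp.  A candidate must additionally be
   differentiated in *both halves* of its span: a historical-recombination
   transition between two-founder tracts mimics three founders over the
   straddling span but leaves some pair undifferentiated in one half.
   These numeric cutoffs are package choices calibrated to the qualitative
   criteria (diversity well above within-founder levels, misassembly
   guard); they are recorded in output metadata.

## Partitioned diversity

Pairwise diversity is the expected per-site allele mismatch (opposite
homozygotes 1, heterozygote comparisons 1/2).  Conversion to per-bp values
uses `pi_site × n_class_sites / (L × class_fraction)`: sites absent from
the table are invariant, and random per-genotype missingness cancels
through the comparable-site normalization.

*Within founding haplotypes*: sites in windows with a direct SAME call.
True shared-founder regions carry no visible differences, so no selection
bias arises; the measured value approximates `theta_selfer × g` (with `g`
the expected shared-founder pair coalescence time) within ~±20%, the excess
coming from misclassified near-identical founder pairs whose few
differences sit inside SAME evidence.

*Among founding haplotypes*: a DIFFERENT interval spans exactly its
supporting differences, so its interior mismatch density is biased upward
wherever other founders contribute interleaved joint sites, and bounding
regions by the pair's own mismatches selects difference-dense sequence at
every scale.  The estimator therefore extends each DIFFERENT evidence block
to the midpoint of the flanking evidence gap (the state transition is
uniformly distributed there), bridges gaps flanked by DIFFERENT evidence on
both sides, and anchors boundaries at SAME evidence, allozygous calls, or
*identity stretches at the invariant-region scale* (≥ 10 identical
outcrosser SNPs over ≥ 25 kb — the run-split scale of 2 kb would excise
chance diversity troughs between genuinely distinct founders and re-inflate
the estimate).  In the long-tract geometry this brings the among-founder
estimate within ≈ 10% of ancestral diversity (its model expectation is
`theta_anc + T·theta_selfer`, about 5% above `theta_anc`); a residual
upward bias of order 5–15% from evidence selection remains and grows as
founder blocks shrink toward the evidence scale.  Confidence intervals
resample assignment regions with replacement.

The within-founder SFS counts derived-allele occurrences among a sample
subset restricted to windows where the subset shares one founder index,
polarized by the outcrosser major allele (ties dropped) or, on synthetic
data, by the true ancestral allele.  Sliding windows (10 kb / 2 kb step,
≥ 100 comparable site-pairs — the minimum-data threshold is a package
default recorded in output metadata) report mean pairwise diversity and the
bp-weighted major-founder frequency; their Pearson correlation is strongly
negative under the founding model.  Patterson's D is the standard
frequency form over derived-allele frequencies with a delete-one block
jackknife (5 cM blocks when a map is present, 1 Mb otherwise).
Neighbor-joining trees (Saitou–Nei, via scikit-bio) use mismatch-fraction
distances, with selfer–selfer entries restricted to SAME/DIFFERENT windows
in the within/among variants.  Genome-wide bootstrap blocks default to
100 kb — larger than outcrosser LD, small enough to leave many blocks.

## Demographic inference

Per grid cell `(k, T)` the engine simulates the truncated coalescent with
common random numbers across cells: epoch durations do not depend on
`(k, T)`, so one set of exponential draws (default 10,000 replicates)
serves the whole grid.  The founder assignment is integrated out exactly —
conditional on the times, all `m` survivors land on one of `k` founders
with probability `k^(1−m)`, which becomes the replicate's weight — so the
surface carries no assignment noise at all and its maximum is not chased
by Monte-Carlo winner's-curse fluctuations.  `P_H1` is the weighted
single-founder probability; the conditional expected SFS follows from
the branch-length identity `E[eta_i] ∝ Σ_j j·t_j·p(i|j,n)` applied to the
truncated epochs (the star join at `T` adds no length), and is validated
against an explicit-topology mutation-dropping oracle and against the exact
lineage-count distribution.  The composite log-likelihood adds a
multinomial SFS term and a binomial single-founder term; the MLE and
2-log-likelihood sets are read off the grid without interpolation,
matching the granularity of the reported estimate.  Composite likelihoods
ignore dependence between observations, so the surface is over-peaked and
the 2-unit set under-covers somewhat; over 50 replicate genomes at
`(k=100, T=1.7)` the scaled-time interval still covers the truth in ≥ 80%
of replicates.

Defaults: grid `T ∈ {0.05, …, 4.00}` step 0.05,
`k ∈ {1..10, 15, 20, 30, 50, 100, 200, 1000}` (the acceptance runs use the
coarser `T ∈ [0.5, 3]` step 0.1, `k ∈ {1,2,5,10,50,100,1000}`); 339
independent regions for the binomial term (one region per cM of a 339-cM
map — a conservative choice, derivable from a supplied map); four
exchangeable samples.  The pipeline measures the single-founder fraction as
the bp fraction of fully painted windows where all samples share one
founder index, and multiplies by the region count; this unit choice is
recorded in the output.

Natural-scale resolution: `N_R = pi_within / (2 μ g)` with
`g = E[pair coalescence time | shared founder]` simulated at the MLE
(closed form `g = [1 − e^{−T}(1+T) + (T/k)e^{−T}] / [1 − e^{−T} + e^{−T}/k]`
used as a cross-check), and `T_f = T · N_R` generations, with the calendar
CI propagated from the scaled-time interval recomputing `g` at each
endpoint.  Defaults `μ = 1.5e-8` per site per generation and one-year
generations; all dates rescale linearly in both.  The closed-form split
time `T_split = (d − π_anc)/(2μ)` is exact arithmetic.

## Numerical and degenerate-input choices

* Missing genotypes are a distinct sentinel (−1), never conflated with 0.
* QC thresholds are inclusive (depth 10 and quality 30 are kept); a table
  without depth/quality annotations passes through with a warning.
* Zero-heterozygote samples, empty grids, cells with no single-founder
  replicates, and unpolarizable tables raise typed errors rather than
  returning silently degenerate values.
* Undefined diversity estimates (no comparable sites, no DIFFERENT
  windows) are flagged, not zeroed.
* Grid likelihoods at impossible observations use a large negative sentinel
  so the arg-max stays well-defined.
* Segment I/O is BED-like 0-based text; internal coordinates are 1-based
  half-open, and round-trips are bit-stable.

## Problem sizes

The test suite and acceptance script run on scaled-down genomes chosen to
keep every Monte-Carlo comparison at ≥ 3-standard-error resolution:
339–2,000 windows (1.7–10 Mb), 10,000 coalescent replicates per grid cell,
10 replicate genomes for the founding-time recovery, 50 for interval
coverage, 40 for the D-statistic null calibration.

## Known limitations

* No recombination within windows and none between founder blocks — the
  simulator cannot produce the gradual block-length decay a real genetic
  map would.
* The diversity partition inherits the evidence-selection bias described
  above; on data whose founder blocks approach the informative-site
  spacing, the among-founder estimate should be treated as an upper bound.
* Near-identical founding haplotypes (ancestral coalescence just before
  the founding) are fundamentally unresolvable; they surface as SAME calls
  and slightly inflate within-founder diversity.
* The binomial composite-likelihood term treats painted regions as
  independent; with real linkage the effective number of regions is
  smaller and the intervals optimistic (the one-region-per-cM convention
  is deliberately conservative for that reason).
* `resolve_natural_scale` assumes the within-founder diversity estimate is
  unbiased; upstream painting contamination propagates directly into
  `N_R` and the calendar founding time.
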