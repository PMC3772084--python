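# founderscan

Founding-haplotype analysis for recently derived selfing species.

When an outcrossing plant lineage gives rise to a predominantly selfing
species, the new species starts from a handful of *founding haplotypes* —
chromosomes sampled from the diverse ancestral population.  Because selfing
suppresses effective recombination, those founding haplotypes persist as
long intact blocks, and for a recent origin much of the variation in the
selfer is still shared with its outcrossing relative.  `founderscan`
exploits this: at sites that segregate in *both* species (jointly
polymorphic sites, almost always incompletely sorted ancestral variation),
two selfer individuals that carry the same founding haplotype must be
identical, and consistent differences diagnose distinct founders.

The package is aimed at population geneticists with a small panel of
resequenced genomes from a selfer/outcrosser pair of a young crucifer-like
system: a handful of selfer samples, a handful of outcrossers, ancestral
synonymous diversity near 2%.  It provides:

* **Genotype model** — VCF + sidecar TSV input (sample metadata, site
  degeneracy annotation, genetic map), quality masking, and
  heterozygosity/allozygosity masking (`founderscan.genotype_model`).
* **Allozygosity segmentation** — a two-state chain over heterozygosity
  indicators separates residual allozygous tracts (clustered heterozygosity
  at between-individual diversity levels) from uniformly scattered
  genotyping error (`founderscan.allozygosity`).
* **Founding-haplotype painting** — pairwise SAME/DIFFERENT runs at jointly
  polymorphic sites (defaults: 4 sites spanning 1.5 kb for SAME, 2
  consecutive differences for DIFFERENT), invariant-region calls, a
  higher-order network assignment with conservative ambiguity propagation,
  and a trio scan for regions carrying more than two founders
  (`founderscan.haplotype_painting`).
* **Partitioned diversity** — synonymous/nonsynonymous pairwise diversity
  within and among founding haplotypes with block resampling, the
  within-founder site frequency spectrum, sliding-window diversity versus
  major-founder frequency, Patterson's D with a block jackknife, and
  neighbor-joining trees (`founderscan.diversity_stats`).
* **Demographic inference** — a coalescent composite likelihood over a grid
  of founding-chromosome count `k` and scaled founding time `T` (units of
  `N_R` generations, `N_R` = effective number of chromosomes):

  * a binomial term for the count of genomic regions where all samples
    trace to a single founder, with probability `P_H1(k, T)`;
  * a multinomial term for the within-founder SFS, whose expected shape is
    `E[eta_i] ∝ Σ_j j·E[t_j]·p(i|j,n)` with
    `p(i|j,n) = C(n−i−1, j−2)/C(n−1, j−1)` over the truncated genealogy;

  plus resolution of the compound time into natural units
  (`pi_within = 2 μ N_R g` with `g` the expected shared-founder pair
  coalescence time) and the closed-form split-time estimate
  `T_split = (d − π_anc) / (2μ)` (`founderscan.demographic_inference`).
* **Synthetic data** — a two-species coalescent simulator of the founding
  model that emits VCF bundles with full ground truth (founder labels per
  window, allozygous tracts, ancestral alleles), so the whole pipeline is
  testable without access to real data (`founderscan.synthetic_data`).
* **Orchestration** — a YAML-configured end-to-end pipeline with a
  deterministic artifact manifest and a threshold sensitivity sweep
  (`founderscan.pipeline`), exposed by the `founderscan` command.

## Worked example

Simulate a four-sample genome of 339 unlinked regions under the founding
model (100 founding chromosomes, scaled founding time 1.7), extract the
model's two observables, and fit the grid:

```python
import numpy as np
from founderscan.synthetic_data import SimParams, simulate_bundle, observations_from_truth
from founderscan.demographic_inference import InferenceConfig, fit_grid, resolve_natural_scale

table, truth = simulate_bundle(SimParams(
    n_selfer=4, n_outcrosser=0, k_founders=100, t_scaled=1.7,
    n_windows=339, err_het=0, miss_rate=0, f_allo=0, seed=11))
sfs, x, n = observations_from_truth(table, truth)
print("within-founder SFS (1,2,3 copies):", sfs.tolist())
print(f"single-founder regions: {x} of {n}")

cfg = InferenceConfig(n_samples=4, n_regions=n,
                      t_grid=np.round(np.arange(0.5, 3.01, 0.1), 10),
                      k_grid=(1, 2, 5, 10, 50, 100, 1000),
                      replicates=10_000, seed=42)
fit = fit_grid(sfs, (x, n), cfg)
print(f"T_hat = {fit.t_hat}  k_hat = {fit.k_hat}  CI_T = {fit.ci_t}  CI_k = {fit.ci_k}")
r = resolve_natural_scale(fit, pi_within=4.1e-4, mu=1.5e-8, generation_years=1.0, seed=1)
print(f"N_R = {r.n_r:.0f} chromosomes   T_f = {r.t_f_years:.0f} years")
```

prints

```
within-founder SFS (1,2,3 copies): [431, 187, 103]
single-founder regions: 243 of 339
T_hat = 1.8  k_hat = 50  CI_T = (1.2, 2.0)  CI_k = (2, 1000)
N_R = 21064 chromosomes   T_f = 37915 years
```

Reading the output: 243/339 regions where all four samples inherited one
founding haplotype pins the scaled founding time near its true value 1.7
(the grid MLE 1.8 sits inside the 2-log-likelihood interval 1.2–2.0), while
the founder count shows the expected long ridge — many values of `k` fit
equally well, though a single founder is excluded.  Resolving with a
within-founder diversity of 0.041% converts the scaled time into roughly
21,000 effective chromosomes and a founding time of ~38 ky.

The same closed-form split-time arithmetic is available from the shell:

```
$ founderscan split-time --d-between 0.0203 --pi-anc 0.0186
split time = 56667 years
```

i.e. net synonymous divergence of 2.03% − 1.86% = 0.17% at
1.5e-8 mutations/site/generation dates the species split to ~57 kya.

Other subcommands (`simulate`, `mask-allo`, `paint`, `stats`, `trio-scan`,
`dstat`, `njtree`, `infer`, `pipeline`, `sweep`) wrap the corresponding
library stages; `founderscan pipeline --config run.yaml` executes the whole
chain (QC → allozygosity mask → painting → partitioned statistics → trio
scan → D/NJ → demographic fit) and writes a manifest with SHA-256 digests
so a rerun with the same config and seed is verifiably identical.

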