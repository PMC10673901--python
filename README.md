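# popdiv

Conservation-genomics analysis of drift-structured metapopulations: the full
desk-side workflow for a reduced-representation (ddRAD-style) SNP survey of a
threatened species whose remnant populations are scattered over islands,
fenced refuges and mainland strongholds — the setting in which managers must
decide which populations matter most for keeping the species' genetic
diversity.

The package provides, as a tested library plus a numbered analysis workflow:

- **SNP/sample filtering**: the standard post-assembly cascade (locus
  presence, max-H<sub>O</sub> paralog screen, one SNP per RAD locus,
  allelic-depth and allele-balance screens, iterative call-rate filtering to
  90% per sample / 95% per SNP, minor-allele-count ≥ 3, technical-replicate
  reproducibility, and close-kin pruning with the allele-sharing
  β̂ "beta-dosage" estimator at β̂ > 0.25).
- **Diversity**: H<sub>O</sub>, unbiased H<sub>E</sub> and π per population
  with variant-only and all-sites denominators, per-population independent
  complete-data re-calling, Hurlbert-rarefied allelic richness
  A<sub>R</sub>, raw and sample-size-standardized private alleles
  P<sub>A</sub>.
- **Differentiation**: windowed and genome-wide π, D<sub>XY</sub> and
  F<sub>ST</sub> (Weir–Cockerham 1984 and Hudson estimators) with
  invariant-site denominators and ratio-of-sums aggregation; isolation by
  distance via a Mantel test of F<sub>ST</sub>/(1−F<sub>ST</sub>) against
  log great-circle distance.
- **Hierarchical partitioning**: a Rao quadratic-entropy "diversity
  cascade" γ = δ + Σ w<sub>r</sub> σ<sub>r</sub>,
  σ<sub>r</sub> = β<sub>r</sub> + Σ w<sub>p</sub> α<sub>p</sub>, with
  Bartlett homogeneity tests of components.
- **Metapopulation contributions**: the gene-diversity partition
  H<sub>T</sub> = H<sub>S</sub> + D<sub>G</sub> (Nei minimum distance) and
  the allelic partition A<sub>T</sub> = A<sub>S</sub> + D<sub>A</sub>
  (pairwise allele absences), leave-one-out percent contributions, and
  optimal population weights for a synthetic pool of 1000 individuals
  maximizing heterozygosity (H) or allele count (k).
- **Prioritization**: alleles as features, populations as planning units,
  exact and greedy maximum-coverage solutions for protecting k of P
  populations, resampled over repeated subsamples of 6 individuals.
- **Synthetic data**: a hierarchical Balding–Nichols generator (strata →
  populations, founder-event translocations by binomial sampling and drift,
  negative-binomial depths, structured missingness, replicate and sib pairs)
  whose latent parameters make every estimator testable against its target.

## Worked example

```python
from popdiv.simulate import simulate_dataset
from popdiv.filtering import run_cascade
from popdiv.differentiation import pairwise_matrix, mantel_ibd

dataset, popmap, truth = simulate_dataset(seed=20, n_loci=1500)
filtered, report = run_cascade(dataset, popmap)
fmap = popmap.restrict_to(filtered.individual_ids)
fst = pairwise_matrix(filtered, fmap, metric="fst", min_n=6)
ibd = mantel_ibd(fst, fmap.coordinates(), permutations=999, seed=20)
print(int(filtered.variant_mask.sum()), "SNPs retained")
print(f"F_ST range {fst.values.max():.3f}; Mantel r={ibd['r']:.3f} p={ibd['p']:.3g}")
```

prints

```
1030 SNPs retained
F_ST range 0.573; Mantel r=0.266 p=0.012
```

1030 of 1500 simulated SNPs survive the cascade; the strongest pairwise
differentiation (0.57) is between the two most drift-isolated island
populations, and linearized F<sub>ST</sub> increases significantly with
geographic distance — the isolation-by-distance signature the simulated
system encodes.

The same workflow as a narrated sequence lives in `analysis/01_simulate.py`
… `analysis/07_prioritize.py` (tables written to `results/`), or as one
configured run: `popdiv run --config <yaml>`. Each stage is also a CLI
subcommand (`popdiv simulate|filter|diversity|dxy-fst|ibd|cascade|
contributions|prioritize`).

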