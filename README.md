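# rohkin

Inference of marriage practice and community size from runs of homozygosity
(ROH), built for small, isolated populations sampled at ancient-DNA scale.

When parents are close kin, their child carries long ROH: tracts where the
two parental haplotypes are identical by descent. For the offspring of
first cousins (inbreeding coefficient F = 1/16) the expected total is
F × G ≈ 222 cM on a G = 3545.75 cM autosomal map, with segments averaging
100/6 ≈ 17 cM. `rohkin` turns this into a cohort-level hypothesis test: in
a sample of n individuals in which each is the offspring of a first-cousin
union with probability r, the one-sided p-value of the observed maximum
statistic is

    p = (1 − r(1 − q))^n,      r* = (1 − α^(1/n)) / (1 − q),

where q is the observed maximum's percentile within a simulated
first-cousin null and r* the largest union rate compatible with the data
at level α. Shorter ROH (4–20 cM) instead reflect the background mating
pool; their per-bin counts follow closed-form intensities λ_bin(Ne) under
a panmictic coalescence model, giving a maximum-likelihood estimate of the
effective community size Ne with a profile-likelihood CI.

The package contains, as importable modules under `src/rohkin/`:

- `genome` — genetic-map coordinates; bundled 22-autosome sex-averaged map
- `pedigree` — gene-dropping simulator with chi-square crossover
  interference (first-cousin / second-cousin / unrelated unions)
- `profiles` — ROH length-bin profiles ([4,8), [8,12), [12,20], >20 cM)
  and coverage filtering (20,000- and 300,000-SNP floors)
- `consang` — individual percentiles, cohort max-statistic test, maximum
  compatible union rate (Monte-Carlo + closed form)
- `ne` — λ_bin(Ne) closed form with Monte-Carlo oracle, Poisson composite
  likelihood, profile-likelihood CI
- `caller` — two-state HMM ROH caller for diploid genotypes, plus a
  synthetic-genotype generator with planted tracts and truth tables
- `kinship` — pairwise-mismatch relatedness, coverage-based genetic
  sexing, burial-unit sex composition
- `eigenstrat`, `io`, `cli` — EIGENSTRAT/PLINK-map/TSV/JSON I/O and the
  `rohkin` command line

Numbered drivers under `analysis/` run the study-scale analyses and write
their tables to `results/`.

## Worked example

```
$ rohkin demo --reps 10000 --seed 0 --out demo.json
sum_gt20: q_fc=0.231 q_sc=0.949 p_mc=0.0054 r*=0.251
longest: q_fc=0.254 q_sc=0.824 p_mc=0.0063 r*=0.258
```

Reading: an individual with 80.3 cM of summed ROH > 20 cM sits at the 23rd
percentile of the simulated first-cousin offspring distribution (`q_fc`) —
within the expected range for a first-cousin union — but at the 95th
percentile of the second-cousin distribution (`q_sc`), so a second-cousin
union explains it comfortably. Yet as the *maximum* of a 14-person cohort
under a 40% first-cousin union rate it is far too small (`p_mc` ≈ 0.006):
that rate is rejected, and the largest compatible rate is `r*` ≈ 25%. The
same logic applied to the longest single segment (34.3 cM) gives p ≈ 0.006
and r* ≈ 26%. The equivalent library calls are `build_null`,
`individual_percentile`, `cohort_pvalue` and `max_compatible_rate` in
`rohkin.consang`.

The same pipeline runs stage by stage:

```
rohkin simulate --union-type first_cousin --reps 1000 --seed 7 --out segs.tsv
rohkin bin --segments segs.tsv --out profiles.tsv
rohkin test-consanguinity --observed-sum 80.3 --observed-longest 34.3 --out report.json
```

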