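# Methods

`rohkin` infers marriage practice and community size in small, isolated
populations from runs of homozygosity (ROH): genomic tracts where an
individual's two parental haplotypes are identical because the parents share
a recent common ancestor. It was built around the archaeogenetic setting of
a ~14-individual medieval island cohort, where the printed observations are
a maximum of 80.3 cM of summed ROH > 20 cM with a longest segment of
34.3 cM, a modern ethnographic first-cousin union rate of ~40%, and a test
level of 0.05. Everything below is exercisable on synthetic data; no
external download is required.

## Coordinate system and default map

All arithmetic happens in genetic-map units. Segments are half-open
intervals [start_cM, end_cM); physical coordinates are annotation only. The
bundled default map is a sex-averaged per-autosome genetic-length table
(GRCh37-era pedigree-map lengths) totalling G = 3545.75 cM over the 22
autosomes. The X chromosome is excluded throughout: the analyses are
autosomal by design. Users can substitute any PLINK `.map` or two-column
chrom/length table; the published percentiles move by a few points across
plausible human maps, which is why the package's own checks use bands
rather than point equalities.

## Gene-dropping simulator

The null distribution of ROH for the offspring of a first-cousin union
(inbreeding coefficient F = 1/16; two shared grandparents) or second-cousin
union (F = 1/64; two shared great-grandparents) is obtained by gene
dropping: every founder haplotype gets a unique label, labels are
propagated through every meiosis of the explicit pedigree, and the
offspring's ROH are the maximal intervals where its two haplotypes carry
the same founder label.

Meiosis uses the chi-square crossover-interference model: chiasmata on the
four-strand bundle form a stationary gamma renewal process with shape
nu = 5 (the classic human interference estimate m = 4) and rate 2 per
Morgan, each involving the transmitted chromatid with probability 1/2. The
gamete therefore sees one crossover per Morgan on average for any nu, and
nu = 1 recovers the no-interference Poisson model exactly (available as a
parameter). Interference matters here: it leaves the mean total ROH at
F x G but thins the right tail of segment lengths. Under pure Poisson
crossovers the first-cousin longest-segment percentile of the observed
34.3 cM comes out near 0.21; with standard interference it is ~0.26, in
line with the published 29th percentile. The simulator assumes full (not
half) cousins, no sex-specific maps, and no obligate chiasma; offspring of
"unrelated" unions carry zero ROH, i.e. all other parental relationships
are treated as too deep to produce segments above the 4 cM floor.

Seeding: one master seed; replicate i derives its own stream
(`SeedSequence(seed).spawn`), and each replicate spawns one stream per
chromosome in genome order, so any replicate is reproducible in isolation
and results do not depend on chromosome processing order.

## Profiles and filtering

Segment lists reduce to per-individual profiles over the length bins
[4, 8), [8, 12), [12, 20] and > 20 cM, plus the summed ROH > 20 cM and the
longest segment. Segments below 4 cM are below the reliable calling floor
for ancient data and are dropped. The exactly-20 boundary belongs to the
[12, 20] bin so the bins partition [4, inf) and total length is conserved;
the "> 20 cM" statistic is strict, which is measure-zero for simulated
data. Coverage floors are inclusive: individuals with >= 20,000 covered
SNPs enter kinship/population analyses, >= 300,000 enter ROH-based
analyses; excluded ids are logged with reasons.

## The two-level consanguinity test

Level 1 places an observed statistic (summed ROH > 20 cM, or longest
segment) in a simulated union-type null as a one-sided lower-tail
percentile q = P(statistic <= observed), ties counted as <=.

Level 2 asks whether the *maximum* over a cohort of n individuals is
unusually small under a first-cousin union rate r. Each cohort member is a
first-cousin offspring with probability r and otherwise contributes 0 (the
deep-pedigree assumption above). Because the cohort maximum is <= the
observed maximum exactly when every consanguineous member falls in the
lower q-tail,

    p = (1 - r (1 - q))^n,

and the largest rate compatible with the data at level alpha is

    r* = (1 - alpha^(1/n)) / (1 - q),

clipped to [0, 1]; q = 1 leaves the rate unbounded and is flagged. The
Monte-Carlo cohort test simulates >= 10,000 cohorts, drawing the
consanguineous members' statistics from the precomputed individual null
(resampling with replacement) — a two-stage Monte Carlo whose cohort maxima
are draws from the same mixture null, at a fraction of the cost of fresh
pedigree simulation per member; it must and does agree with the closed form
within binomial sampling error. The closed-form path makes the reported q,
p and r* satisfy their defining identities to machine precision, and r* is
computed in closed form rather than by bisection over Monte Carlo so the
output is deterministic given q.

Defaults are the study conditions: n = 14, r = 0.40, alpha = 0.05, with
10,000 replicates (the original analysis used 1,000; more replicates only
tighten Monte-Carlo error, and `--reps` restores any size).

## Effective population size from intermediate ROH

Background ROH arise when the two parental lineages of an individual
coalesce recently in a small randomly-mating community. The model: the
lineage pair coalesces t generations back with prior
P(t) = (1/2Ne)(1 - 1/2Ne)^(t-1); conditional on t, recombination over 2t
meioses breaks the shared genome as a Poisson process of rate 2t per
Morgan, and the expected number of resulting pieces longer than x cM on a
chromosome of length L is (1 + rho (L - x)) e^(-rho x) with rho = 2t/100.
Summing over the prior gives closed-form per-bin intensities
lambda_bin(Ne), strictly decreasing in Ne. The prior is truncated at
50 Ne generations and renormalized; terms beyond t = 2000 contribute
< 1e-12 to bins >= 4 cM and are skipped.

Counts in the bins [4, 8), [8, 12), [12, 20] are modeled as independent
Poisson across bins and individuals — a composite likelihood, so the CI is
approximate. Bins > 20 cM are excluded: long ROH belong to the close-kin
process and would bias Ne downward. The MLE maximizes the Poisson
log-likelihood on a 400-point log-spaced grid over [50, 1e5] with bounded
refinement; the 95% CI is the profile-likelihood interval at a drop of
1.92. All-zero counts leave a monotone likelihood; the result is then
flagged censored with an unbounded upper CI rather than forced.

Two generators accompany the model. The Monte-Carlo *oracle* for
lambda_bin draws one t per replicate and simulates breakage literally, and
must match the closed form within 3 SE (verified at Ne = 250/500/1000).
The *cohort generator* used for recovery experiments instead draws per-bin
Poisson counts with intensity lambda_bin(Ne) and segment lengths from the
model's within-bin length density: along a real genome coalescence times
form a mosaic across loci, so per-individual counts are near-Poisson, not
the all-or-nothing outcome a single genome-wide t would give (under which
no estimator resembling this likelihood recovers Ne at n = 14). At
Ne = 600, n = 14: CI coverage ~92/100 and median relative bias under 2%.
Reproducing a specific published point estimate requires that study's
per-individual ROH table, which is not bundled; the estimator is validated
by within-model recovery instead.

## Diploid ROH caller

A two-state HMM (non-ROH / ROH) over diploid genotypes with per-site
allele frequencies f: non-ROH emits Hardy-Weinberg [(1-f)^2, 2f(1-f), f^2];
ROH emits [(1-e)(1-f), e, (1-e)f] with heterozygote floor e = 0.01
absorbing genotyping error. Transitions over a gap of d cM follow the
two-state continuous-chain solution with rates 1/100 per cM into and 1/10
per cM out of ROH; forward-backward runs in log space; posterior >= 0.5
defines ROH sites; runs shorter than 4 cM are dropped. Missing calls emit
uninformatively.

The caller is diploid-only on purpose: the real study's data are
pseudo-haploid and need a haplotype-copying model with an external
reference panel, which is out of scope; pseudo-haploid input raises. The
synthetic-genotype generator plants known autozygous tracts (both
haplotypes share one draw inside a tract), flips alleles with probability
epsilon and applies missingness, emitting a truth table. Benchmarks: at 20
markers/cM and epsilon = 0.01, precision and recall are 1.0 for planted
segments >= 8 cM (50 tracts, 20 individuals); boundary error with
informative markers is ~2 marker intervals on average — posterior decoding
cannot localize a boundary more finely than the uninformative homozygous
run flanking a tract, so exact single-interval boundary agreement is not
an attainable target for any decoder.

## Kinship and genetic sex

Pairwise mismatch rate (pmr): the fraction of overlapping non-missing
autosomal sites where two individuals' single sampled alleles differ.
Against the cohort baseline B (median pmr after one iteration of excluding
pairs already below the second-degree boundary), expected ratios are 0.50
(identical / same individual sampled twice), 0.75 (first degree), 0.875
(second degree), 1.0 (unrelated); calls use midpoint boundaries
(0.625 / 0.8125 / 0.9375), with "insufficient data" below 15,000
overlapping sites. These thresholds are design choices standard for the
method; the source analyses do not print theirs.

Genetic sex uses coverage ratios normalized by autosomal coverage:
XX when X in [0.8, 1.2] and Y < 0.05; XY when X in [0.4, 0.6] and Y in
[0.3, 0.7]; anything else is explicitly indeterminate. The burial-unit
summary counts multi-individual units and how many contain both sexes.

## What the synthetic data do and do not show

The generators emulate: recombination with interference on a realistic
map, pedigree-structured autozygosity, allele-frequency-driven genotypes
with error and missingness, pseudo-haploid sampling, and model-consistent
background ROH. They do not emulate: linkage disequilibrium or haplotype
structure (sites are frequency-independent), ancient-DNA damage profiles,
reference bias, variable per-individual coverage, or population structure.
Passing tests therefore demonstrate correctness of the algorithms and
internal consistency of the statistics, not end-to-end performance on real
ancient DNA — for that the field-standard callers with reference panels
remain necessary.

## Numerical conventions

Interchange TSVs carry cM with 4 decimals and a metadata header (package
version, seed, parameter hash); writers stage-and-rename so failures leave
no partial files, and refuse to overwrite without force. EIGENSTRAT `.snp`
stores Morgans (column 3), converted to cM on read. Emissions are floored
at 1e-12 in likelihood space; the Ne likelihood floors intensities at
1e-300 before logs. Problem sizes in the shipped analyses (10,000-replicate
nulls, 50-100 recovery repetitions, 20-individual caller benchmarks) were
chosen so each stage's Monte-Carlo error is small relative to the decision
bands it feeds.
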