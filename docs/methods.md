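# Methods

## The question and the data model

Dominant marker systems (SCoT, ISSR, RAPD, dominantly scored AFLP) produce,
for every individual, a binary profile over amplified fragments: band
present (1) or absent (0). Heterozygotes cannot be told apart from dominant
homozygotes, so every statistic in this package works directly on band
carrier frequencies rather than on genotype frequencies. The container is
the `BandMatrix`: an `n_individuals x n_bands` 0/1 matrix with a population
label per individual and a primer label (optionally a fragment size) per
band. Only curated, reproducible bands belong in a matrix; a missing or
non-binary cell is a hard error and is never imputed.

The driving question is a germplasm-collection design problem: how many
individuals must be sampled from one population so that the sample retains
most of the population's marker diversity? The package answers it with
random-subsampling retention curves backed by an exact combinatorial
expectation, and surrounds that core with the diversity, differentiation,
clustering and model-based-structure analyses such a study reports.

## Diversity statistics

Bands are pooled as alleles of a single phantom multi-allelic locus with
*occurrence-proportional* frequencies `p_j = count_j / sum_k count_k`. This
estimator is fixed by its behaviour at a sample of one individual: a single
plant exhibiting `Na` bands has uniform frequencies `1/Na` and expected
heterozygosity exactly `1 - 1/Na`, which matches how such tables are
printed at sampling size 1 (67 bands -> 0.9851). No small-sample
(`n/(n-1)`-type) correction is applied: the correction is undefined at
n = 1, the one place where the estimator is anchored.

- `He = 1 - sum p_j^2` (Nei gene diversity on pooled frequencies).
- `PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2` (Botstein), computed via
  the algebraic rewrite `1 - S2 - (S2^2 - S4)` with `S2 = sum p^2`,
  `S4 = sum p^4`; `PIC <= He` always, with equality only when monomorphic.
- `PPB`: percentage of observed (count > 0) bands with `0 < count < n`.
- Shannon index `I`: mean per-band binary entropy
  `-(q ln q + (1-q) ln(1-q))`, `q` the carrier fraction; fixed or absent
  bands contribute zero. The mean runs over all bands of the matrix.
- Resolving power per primer: `Rp = sum_b (1 - 2|0.5 - q_b|)`, largest for
  bands near 50% frequency.

Statistics over "all primers" pool bands across primers; per-primer
variants restrict to one primer's bands. He and PIC are reported to four
decimals and retention percentages as whole percents, the conventional
table formats.

## Rarefaction and the Reserve Percentage

At each size `n` of a sampling ladder (default 1, 2, 3, 5, 8, 10, 20, 30,
40, 50, 60 — dense where the curve rises, coarse along the plateau),
`subsample_curve` draws replicate subsamples *without replacement* within
one population (with replacement the full-sample band count could not be
recovered exactly at `n = N`) and reports mean and SD of Na, RP, He and
PIC. `RP = 100 * Na(sub)/Na(full)` is rounded half away from zero to a
whole percent. The replicate count defaults to 200; `replicates=1` is the
single-draw mode that mimics how a field study would fill a table. The
reference Na is the population's own full sample, not the pooled union
across populations.

Every Monte-Carlo curve is checked against the exact expectation: a band
carried by `c` of `N` individuals is missed by a uniform `n`-subsample with
hypergeometric probability `C(N-c, n)/C(N, n)`, so
`E[Na(n)] = sum_b [1 - C(N-c_b, n)/C(N, n)]`, strictly increasing in `n`
until every band is recoverable. `plateau_size` returns the smallest ladder
size whose mean RP reaches a threshold (90% in the headline use).

## AMOVA and Phi_ST

Differentiation uses the one-level variance decomposition of pairwise
squared Euclidean distances (for 0/1 profiles, the count of mismatched
bands): `SS_total = (1/N) sum_{i<j} d2`, within-group sums analogously per
population, mean squares `sigma2_w = SS_w/(N-G)` and
`sigma2_a = (SS_a/(G-1) - sigma2_w)/n0` with
`n0 = (N - sum n_g^2/N)/(G-1)`, and `Phi_ST = sigma2_a/(sigma2_a +
sigma2_w)`. A two-level "among species" stratum would be vacuous for a
single-species design, so only the among/within-population level is run; a
caller can still pass any grouping vector. The among-group component is
reported as estimated (possibly slightly negative) and clamped to zero only
inside the Phi ratio, the usual convention. Significance permutes
individuals among populations (default 999 permutations) with the add-one
p-value estimator `(1 + #{Phi_perm >= Phi_obs})/(1 + P)`.

The per-sampling-size FST sweep subsamples `n` individuals per population
and recomputes Phi_ST. Because a per-accession FST is not a well-defined
quantity, the sweep offers two explicit contrasts: `focal_vs_rest` (each
accession against the pooled remainder; one column per accession, the
layout such studies tabulate) and `global` (one among-all value). Size-1
rows are reported as 0.00 by convention — one individual per group leaves
no within-group variance to partition.

## Clustering

Jaccard similarity `J = a/(a+b+c)` ignores shared absences, which carry no
information for dominant markers; `1 - J` feeds UPGMA. The UPGMA
implementation is in-package: reproducible trees need a fixed,
platform-independent tie-break (lexicographically smallest index pair at
equal merge distance), which off-the-shelf linkage routines do not
guarantee; tests verify it against both `scipy.cluster.hierarchy` and an
independent naive agglomerator. Node height is merge distance / 2, making
the tree ultrametric; cophenetic distances of an already-ultrametric input
are reproduced exactly.

Bootstrap support resamples *bands* (columns) with replacement: the tips
are individuals and the characters are bands, so the character dimension is
the resampling unit. Each original internal bipartition's support is the
percentage of replicate trees containing the same leaf set (default 1000
replicates). Supports below 50% are conventionally suppressed in drawings
but retained in the data structure. In a bootstrap replicate an individual
can lose all its bands; such profiles get similarity 0 to non-empty
profiles (1 to equally-empty ones) so replicates stay well defined —
negligible in practice at realistic band counts.

Newick export writes branch lengths as height differences and supports as
internal node labels; `read_newick` (via dendropy) round-trips topology,
heights and supports.

## Admixture model and Evanno delta-K

The model-based clustering is a lightweight Bayesian admixture model for
binary characters: `q_i ~ Dirichlet(1,...,1)` membership per individual,
latent origin `z_ij ~ Categorical(q_i)` per band observation, score
`x_ij ~ Bernoulli(theta[z_ij, j])`, `theta ~ Beta(1,1)`. Bands are modelled
directly as Bernoulli characters; no recessive-null-allele reconstruction
is attempted. All conditionals are conjugate, so inference is plain Gibbs
sampling over `z`, `q`, `theta`. The per-sweep data log-likelihood with `z`
integrated out is averaged over post-burn-in sweeps as `L(K)`.

Defaults are 2000 total sweeps with 500 burn-in — deliberately desk-scale;
chains on separable data mix within tens of sweeps because every update is
conjugate, and longer runs are one argument away. The Dirichlet
concentration is fixed at 1 (no alpha inference). Internals run in float32
(the sweep is memory-bound; `theta` lives well inside (0,1)) with
log-likelihoods accumulated in float64.

`run_grid` spawns deterministic child seeds from one master seed for
`runs_per_k` independent runs at each K. `evanno_delta_k` computes
`deltaK(K) = mean_runs |L(K+1) - 2 L(K) + L(K-1)| / SD_runs(L(K))`, pairing
runs by index, and selects the interior argmax (ties toward smaller K). A
flat likelihood profile (all second differences zero) yields `best_k =
None` — "no signal" — and a vanishing run SD is flagged as degenerate.

## Synthetic data generator

The generator emulates a four-accession, 60-individuals-per-accession
survey scored at five primers with 25, 21, 29, 23 and 24 bands (122 total).
For each population and each shared band an independent presence
probability is drawn from a mixture: common bands `U(0.35, 0.65)`, rare
bands `U(0.02, 0.15)`, rare fraction 0.3. Drawing the mixture independently
per (population, band) lets the same band be common in one accession and
rare in another, which is the main source of realistic differentiation. On
top, each population owns 6 private bands (`U(0.5, 0.9)` inside the owner,
exactly 0 elsewhere), allocated round-robin across primers. The private
count was chosen by an a-priori variance-component calculation so the
expected Phi_ST lands near 0.3, inside the 0.25-0.45 window reported for
strongly structured selfing-species accessions; realized values sit around
0.28. Scores are independent Bernoulli draws — bands are unlinked, which is
adequate because every supported statistic is single-band or
frequency-based.

Under these defaults the realized per-population band counts come out near
102-104 (the emulation target span is 99-116) and expected retention at
n = 10 is ~86-92% of the realized full-sample count, i.e. the curves
saturate near ten individuals as in the motivating study design.
`calibrate_to_saturation` checks the *unconditional* expected RP at n = 10
(a band with probability `p` enters an `n`-subsample with probability
`1 - (1-p)^n`) against the band [88%, 97%] and lowers `rare_fraction` in
0.01 steps if retention is too slow; a spec that saturates too fast is
flagged rather than adjusted, since adding rare bands would distort the
intended frequency spectrum. `generate_homogeneous` draws one frequency
vector shared by all populations (no privates) — the exact null for
type-I-error checks of differentiation statistics.

What the generator does **not** emulate: linkage between bands, scoring
error/missing bands, the mixed selfing mating system behind real
accessions, and per-primer heterogeneity of the frequency spectrum. In the
real study the resolving power per primer spanned 2.67-13.90, implying many
bands at extreme frequencies for some primers; under the homogeneous
mixture here, expected per-primer Rp is roughly proportional to band count
(~13-19) and does not reproduce that span. Passing tests therefore
demonstrate correctness of the estimators and the qualitative study
behaviour (saturation near n = 10, four recoverable clusters, Phi_ST in
the range typical of strongly structured accessions), not distributional
fidelity to any particular real data set.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng` seeds;
  derived seeds use `SeedSequence` spawning and are kept below 2^31. Same
  seed, same inputs -> bit-identical results, including the report bundle
  (the pipeline writes no timestamps).
- RP rounding: half away from zero (`floor(x + 0.5)`), so 89.52 -> 90.
- UPGMA ties: smallest (row, column) index pair, found by row-major argmin.
- Degenerate AMOVA inputs: a population of size 1 is an error (zero
  within-group degrees of freedom); identical constant data yields Phi = 0.
- Permutation p-values use the add-one estimator and can never be 0.
- Sizes used in the shipped checks: rarefaction oracle comparisons at 500
  replicates on 60-individual populations plus exhaustive enumeration on an
  8-individual fixture; delta-K recovery on the default 240 x 122 matrix
  over K = 2..6 with 5 runs of 2000 sweeps per K, repeated for 10 master
  seeds; null AMOVA calibration over 50 simulations of 4 x 20 individuals.

## Known limitations

- The occurrence-proportional allele pooling is an estimator convention,
  not an inference of underlying codominant allele frequencies; He/PIC
  values are comparable across subsets scored with the same bands but not
  with Hardy-Weinberg-based estimates.
- The admixture sampler uses no label-alignment (CLUMPP-style) across
  runs; only likelihoods and per-run memberships are compared, which is all
  delta-K needs.
- One-level AMOVA only; hierarchical (species-level) designs must be
  expressed through the grouping vector.
- The FST sweep's per-accession column is a focal-vs-rest contrast, one of
  several possible conventions for tabulating a per-accession fixation
  index.
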