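# bandpop

Sampling-size optimisation and population-genetic analysis of **dominant
(presence/absence) molecular markers** — SCoT, ISSR, RAPD and dominantly
scored AFLP band matrices.

Germplasm surveys and core-collection programmes face a standing design
question: *how many individuals must be sampled from one population so the
sample captures most of that population's genetic diversity?* Sampling too
few plants discards alleles; sampling too many multiplies the cost of
maintaining and regenerating the collection. `bandpop` answers the question
for dominant-marker data and ships the complete analysis stack such a study
reports:

- **Band matrices** (`bandpop.matrix`) — individuals x bands 0/1 scores
  with primer and population annotations, as validated CSV/TSV.
- **Diversity statistics** (`bandpop.diversity`) — observed alleles *Na*,
  percentage of polymorphic bands *PPB*, expected heterozygosity
  *He* = 1 − Σp², Botstein polymorphism information content
  *PIC* = 1 − Σpᵢ² − Σᵢ<ⱼ2pᵢ²pⱼ², Shannon index *I* (mean per-band binary
  entropy) and per-primer resolving power Rp = Σ(1 − 2|0.5 − q|), all on
  occurrence-proportional pooled allele frequencies.
- **Rarefaction** (`bandpop.rarefaction`) — random subsampling without
  replacement over a ladder of sizes, tracking Na, He, PIC and the
  **Reserve Percentage** RP = 100·Na(sub)/Na(full), with the exact
  hypergeometric expectation E[Na(n)] = Σ_b[1 − C(N−c_b,n)/C(N,n)] as an
  analytic oracle and plateau detection.
- **Differentiation** (`bandpop.amova`) — one-level AMOVA on mismatch
  distances, Φ_ST (reported as F_ST) with permutation p-values, and the
  F_ST-vs-sampling-size sweep.
- **Clustering** (`bandpop.cluster`) — Jaccard similarity, UPGMA
  ultrametric dendrograms with reproducible tie-breaking, band-bootstrap
  clade supports, Newick I/O.
- **Admixture** (`bandpop.admixture`) — a conjugate Gibbs sampler for a
  Bayesian admixture model of binary band characters, multi-run grids over
  K and **Evanno ΔK** selection of the number of clusters.
- **Synthetic data** (`bandpop.synth`) — a generator with stored ground
  truth emulating a four-accession, 60-individuals-each, five-primer,
  122-band survey, so the whole pipeline runs and is testable with no
  external data.
- **Pipeline + CLI** (`bandpop.pipeline`, `bandpop` command) — one seeded
  config in, a byte-reproducible bundle of TSV tables, a Newick tree and a
  run log out.

## Worked example

```python
import bandpop as bp

# a synthetic survey: 4 accessions x 60 individuals, 122 bands, 5 primers
m, truth = bp.generate(seed=7)

curve = bp.subsample_curve(m, "LJ. 1", replicates=200, seed=7)
print(curve.summary())

res = bp.phi_st_permutation(m, n_permutations=199, seed=7)
print(res.summary())
```

prints (abridged):

```
Rarefaction of population 'LJ. 1' (200 replicates per size, reference Na = 102)
      na_mean   na_sd  rp_mean   rp_sd  he_mean   he_sd  ...  expected_na
size
1      40.625  4.8385   39.625  4.8385   0.9750  0.0031  ...      40.2833
5      82.300  2.6315   80.330  2.5581   0.9851  0.0006  ...      82.2992
10     91.280  2.0303   89.280  2.0303   0.9863  0.0003  ...      91.3810
20     97.725  1.6007   95.725  1.6007   0.9869  0.0002  ...      97.6465
60    102.000  0.0000  100.000  0.0000   0.9873  0.0000  ...     102.0000

Analysis of molecular variance
                     df           SS   variance  pct_total    Phi_ST      p
among populations     3  1288.845833   6.833763  25.862699  0.258627  0.005
within populations  236  4623.116667  19.589477  74.137301       NaN    NaN
Phi_ST = 0.2586, p = 0.005 (199 permutations)
```

Reading it: a single plant of this population shows ~40 of its 102 bands;
ten random plants already retain ~89% of them (the Monte-Carlo mean tracks
the exact expectation `expected_na` closely), and the curve is flat well
before the full 60 — retention crosses 90% between sizes 10 and 20, while
He is within 0.001 of its final value from ten plants on. About 26% of the
molecular variance lies among the four accessions (Φ_ST = 0.26,
permutation p = 0.005). Real band matrices enter the same way through
`bp.read_band_matrix("scores.csv")`.

The admixture grid asks how many clusters the data support:

```python
fits = bp.run_grid(m, k_min=2, k_max=6, runs_per_k=5, seed=11)
print(bp.evanno_delta_k(fits).summary())   # best K = 4 on this data
```

The same analyses are available from the shell:

```sh
bandpop generate --seed 7 matrix.csv
bandpop rarefy matrix.csv --population "LJ. 1" --seed 7
bandpop amova matrix.csv --seed 7
bandpop structure matrix.csv --k-max 6 --runs-per-k 5 --seed 11
bandpop run-all config.yaml
```

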