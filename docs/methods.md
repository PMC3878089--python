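# Methods

## The scan

`xpscan` maps footprints of recent strong (artificial) selection in a set of
reproductively isolated subpopulations ("breeds") genotyped on a medium-density
SNP chip, using cross-population extended haplotype homozygosity (XP-EHH).

**EHH.** For a core SNP and a target marker, EHH is the probability that two
randomly drawn haplotypes are identical at every marker from the core to the
target (inclusive). Within each population the curve starts at the core-allele
homozygosity and is non-increasing outward. Genetic distance is taken as
physical distance times 1 cM/Mb (1 bp = 1e-8 Morgan), the standard proxy when
no genetic map is available for the chip.

**XP-EHH.** For an ordered (case, control) pair of breeds, each breed's EHH
curve is integrated by trapezoids against genetic distance, extending marker
by marker on both sides of the core. A side stops when the EHH of the
*combined* case+control sample falls below a cutoff (default 0.05; the
stopping marker's trapezoid is still counted) or the chromosome ends. The raw
score is `ln(I_case / I_control)`; positive values indicate unusually long
haplotype homozygosity — i.e. candidate selection — in the case breed. Raw
scores of one ordered comparison are standardized genome-wide to zero mean
and unit (population) variance (sXPEHH). By construction
`sXPEHH(A vs B) = -sXPEHH(B vs A)` at every SNP. There is no maximum
inter-marker gap by default (`max_gap_bp` is available for sparse maps).

**Empirical significance.** Two breeds without organised directional breeding
("calibration" breeds) calibrate what drift alone can achieve: for every
(control breed, chromosome) the threshold is the mean of the maximum sXPEHH
the two calibration breeds reach as case breeds against that control on that
chromosome. A case SNP is significant for a control when its sXPEHH strictly
exceeds that threshold; nSC counts the controls for which a SNP is
significant. Because each comparison is standardized to ~N(0,1), the
calibration maxima are essentially the extreme order statistics of the null —
a case breed's sweep must therefore out-score its *own* genome-wide drift
maxima to be called. Only the positive tail is tested for the case breed; the
negative tail belongs to the reversed comparison, scored separately.

**Signatures.** Significant SNPs (nSC ≥ 1, pooled over controls) merge into a
signature when separated by at most one non-significant SNP. Intervals extend
by half the physical distance to the neighbouring non-significant marker on
each side (floor/ceil of the midpoint so closed intervals never shrink); a run
touching the chromosome's first marker extends to bp 1, one touching the last
marker extends to that marker's position. Signatures with exactly one
significant SNP ("singletons") are kept only when confirmed against more than
one control (nSC ≥ 2). Genes overlap-annotate by any base-pair overlap with
the extended interval; BED input (0-based half-open) is converted to 1-based
inclusive internally. The chromosome-name check errors only when the
signature and gene chromosome sets are fully disjoint (a naming-convention
clash); gene-poor chromosomes are legal.

## Supporting summaries

**Marker QC.** Markers are dropped, first matching reason wins, when they
have (i) no map position, (ii) minor allele frequency below 0.0023 across all
individuals pooled, or (iii) per-marker genotype call rate below 0.90. All
comparisons are strict, so boundary values survive.

**Relatedness pruning (UAR).** The unified additive relationship between
individuals j, k uses within-breed allele frequencies p_i and dosages
x ∈ {0,1,2}:

    UAR_jk = mean_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i))

with the companion single-individual diagonal
`1 + mean_i (x² − (1+2p)x + 2p²)/(2p(1−p))`. One animal is removed per
iteration — most partners at/above the 0.20 threshold, ties by larger maximum
UAR, then by later input order — until no pair reaches 0.20. Note the exact
finite-sample property of in-sample frequency estimates: for unrelated
individuals the mean off-diagonal is −1/(n−1), not 0 (the tests assert this).

**F_ST.** Pairwise Weir–Cockerham (1984) variance-components theta,
multi-locus as the ratio of summed `a` over summed `a+b+c`, loci monomorphic
in the pooled pair skipped. Small negative values are a known estimator
property. The matrix report includes a per-breed mean row.

**PCA.** Covariance PCA (SVD) of mean-centered −1/0/1 genotype codes, missing
values imputed at the column mean; per-component variance shares are
reported.

**Ne from LD.** Within a breed, markers with MAF < 0.10 are excluded; r² is
computed from phased haplotype frequencies (`D²/(p_A q_A p_B q_B)`, equal to
the squared Pearson correlation of the 0/1 haplotype columns). Pairs with
physical distance in [975 kb, 10,025 kb) enter half-open 50-kb bins
(181 bins, midpoints 1–10 Mb). With n = 2 × analysed animals and
c = bin-midpoint distance in Morgan,

    Ne = ( 1/E(r²) − 1/(n−1) − 1 ) / (4c),

referring to 1/(2c) generations ago: 50 generations at the 1 Mb bin ("Ne50")
down to 5 at the 10 Mb bin ("Ne5"). The formula is implemented exactly as
printed in the source method (the sample-size term subtracts from 1/E(r²),
not from r²). Working from phased haplotypes rather than a genotype-EM
estimator is a documented divergence; with known phase the haplotype
estimator is exact.

**Correlations.** Pearson r between breed-level series (signature counts,
SNPs per signature, Ne5, Ne50, Ne5/Ne50) with two-sided p from the t
transform with n−2 df.

## The synthetic generator

A discrete forward Wright–Fisher simulator supplies panels with known truth:

- Marker maps with exponential inter-marker gaps (default mean 48.78 kb, the
  spacing of a 54k bovine chip), one or more chromosomes.
- A common founder pool (default 500 diploids) with allele frequencies
  uniform on (0.05, 0.95) — chip SNPs are ascertained common variants — and
  founder haplotypes in linkage equilibrium; LD accrues by drift during the
  simulated epoch.
- Per-breed linear diploid-size trajectories (monoecious random mating,
  selfing allowed); crossover counts Poisson with mean equal to the
  chromosome's genetic length, positions uniform.
- Sweeps: the favoured allele multiplies a parent's sampling weight by
  (1+s) per copy. Planting at a standing frequency places all initial copies
  on a *single ancestral background* (carriers receive a copy of one focal
  haplotype over ±`origin_window` markers around the core) — a hard sweep has
  one origin, and scattering the allele over random backgrounds would emulate
  a soft sweep, which by design leaves little extended-homozygosity signal.
- One seeded generator drives all draws in a fixed documented order, so runs
  are bit-reproducible.

What the generator does **not** emulate: mutation during the epoch, gene
conversion, overlapping generations and unequal sex ratios, real bovine
chromosome lengths and marker ascertainment beyond the founder spectrum,
genotyping error, and phasing error (phase is known exactly). Passing
recovery tests therefore show the pipeline's decision layer behaves correctly
on idealized hard sweeps, not that real-data power equals the simulated
power; in particular phased-input quality and SNP-density gaps materially
affect real scans.

## Recovery-test conditions (the package's chosen study sizes)

- *Sweep recovery*: six breeds — one case (500→100 diploids over 40
  generations), three controls (450–550 → 90–120), two calibration breeds
  (1700→185, 1000→150) — 30 individuals sampled per breed; 1000 markers on 5
  chromosomes; sweep with s = 1.5 per copy from standing frequency 0.02
  starting at generation 25 (active over the final 15 generations), origin
  window ±60 markers. The bar: the planted core lies inside a final
  signature in ≥ 80% of 20 seeded replicates. The sweep must beat the case
  breed's own drift maxima (that is what calibration thresholds measure), so
  the regime is deliberately a young, strong, nearly fixed hard sweep — the
  configuration XP-EHH is designed to detect.
- *Neutral specificity*: the same design without a sweep; final signatures
  must cover < 5% of the genome in every replicate.
- *Localization*: with a compact origin (±15 markers) the genome-wide maximum
  sXPEHH lies within 1 Mb of the planted core in ≥ 16/20 replicates.
- *Ne recovery*: constant N = 200 for 90 generations (about twice the
  1 Mb bin's 50-generation time depth, so LD at that distance has
  equilibrated from the linkage-equilibrium founders), 1500 markers on 2
  chromosomes, 100 sampled individuals; the 1 Mb-bin estimate (Ne50) is
  within ±30% of truth averaged over 10 seeds.

QC is applied inside these runs; UAR pruning is disabled (simulated
individuals are drawn without close-relative structure, and pruning would
only shrink sample sizes).

## Numerical choices

- EHH pair probabilities are exact ratios of pair counts; the fast scorer
  (numba-compiled partition refinement) is asserted exactly equal to the
  pure-Python reference integrator.
- Haplotypes with missing alleles drop out of a walk from the first missing
  marker onward; EHH is undefined (NaN, distinct from 0) with fewer than two
  considered haplotypes. SNPs not segregating in a pooled comparison, or
  with a zero integral, score NaN and are excluded from standardization.
- Standardization uses the population (divide-by-N) standard deviation.
- Thresholds use strictly-greater comparisons; ties are measure-zero.
- Signature boundary midpoints floor (left) / ceil (right) to integers.
- The pipeline is a pure function of (inputs, config, seed); stage outputs
  are TSV plus a manifest of SHA-256 hashes, and re-runs are byte-identical.

## Known limitations

- Power against *soft* sweeps (many origins) is intrinsically poor — a
  property of the statistic, reproduced faithfully here.
- Small genomes make the calibration thresholds relatively harsher: with M
  SNPs the threshold is the mean of two maxima of ~M standard normals, while
  a sweep's standardized score is bounded by the comparison's own drift
  variance. The recovery conditions above reflect that trade-off.
- Ne-from-LD uses the printed estimator verbatim; it is biased for strongly
  declining populations (it reads a time-indexed average) and its absolute
  scale depends on the r² estimator used.
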