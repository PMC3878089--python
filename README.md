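# xpscan

Genome-wide scanning for signatures of recent strong artificial selection in
subdivided livestock populations, built around cross-population extended
haplotype homozygosity (XP-EHH).

Modern breeds are small, reproductively isolated subpopulations under intense
directional selection. A beneficial allele rising quickly drags a long,
frequent haplotype with it. For a core SNP and an ordered (case, control)
breed pair, each breed's EHH curve — the probability that two random
haplotypes are identical from the core out to a given marker — is integrated
against genetic distance (1 cM/Mb physical proxy), and

```
XP-EHH = ln( I_case / I_control ),        sXPEHH = (XP-EHH − μ) / σ
```

standardized genome-wide per comparison. Positive extremes mark candidate
selection in the case breed. Instead of an arbitrary empirical cutoff,
significance thresholds come from two *artificially unselected* calibration
breeds: per control breed and chromosome, the threshold is the mean of the
maximum sXPEHH the two calibration breeds achieve as cases — the level drift
alone can reach. Significant SNPs (strictly above threshold, pooled over
controls with per-SNP confirmation counts nSC) merge into signatures
tolerating single-SNP gaps, extend half-way to the flanking non-significant
markers, and singletons survive only when confirmed against more than one
control. The package also provides the supporting population-genetic
summaries: UAR genomic-relationship pruning (< 0.20), pairwise
Weir–Cockerham F_ST, PCA of −1/0/1 genotypes, and effective population size
from binned LD decay, `Ne = (1/E(r²) − 1/(n−1) − 1)/(4c)`, read at
1/(2c) = 5…50 generations ago — plus a forward Wright–Fisher simulator of
breed-structured panels with plantable hard sweeps and known truth.

## Worked example

```python
import xpscan as xs

# a six-breed panel: one case with a planted hard sweep, three controls,
# two large-Ne calibration breeds; 1000 SNPs on 5 chromosomes
cfg = xs.SimConfig(
    breeds=[xs.BreedConfig("CASE", 500, 100, 40, 30),
            xs.BreedConfig("C1", 500, 100, 40, 30),
            xs.BreedConfig("C2", 450, 120, 40, 30),
            xs.BreedConfig("C3", 550, 90, 40, 30),
            xs.BreedConfig("CAL1", 1700, 185, 40, 30, role="calibration"),
            xs.BreedConfig("CAL2", 1000, 150, 40, 30, role="calibration")],
    n_markers=1000, n_chromosomes=5,
    sweeps=[xs.SweepTruth("CASE", 100, s=1.5, start_gen=25,
                          initial_freq=0.02, origin_window=60)],
    seed=0)
panel, truth = xs.simulate_panel(cfg)

scan = xs.SelectionScan(panel, xs.ScanConfig(do_prune=False))
res = scan.fit(case_breeds=["CASE"])
print(res.thresholds.table.head(3).round(3).to_string(index=False))
for s in res.signatures_final["CASE"]:
    print(f"BTA{s.chrom}:{s.start_bp:,}-{s.end_bp:,}  "
          f"{s.n_snps} SNPs  nSC={max(s.nsc)}")
print("planted core:", f'{panel.markers.position_bp[100]:,}',
      "final frequency:", truth.sweep_final_freq[("CASE", 100)])
```

prints

```
control chrom  max_cal1  max_cal2  threshold
     C1     1     2.868     2.777      2.822
     C1     2     1.919     3.147      2.533
     C1     3     3.296     3.621      3.459
BTA1:2,366,365-2,495,564  5 SNPs  nSC=1
BTA1:2,793,741-3,338,671  18 SNPs  nSC=2
BTA1:3,742,914-8,960,678  84 SNPs  nSC=2
planted core: 5,788,889 final frequency: 1.0
```

The sweep fixed (frequency 1.0) and the planted core at 5.79 Mb on
chromosome 1 falls inside the third called signature — 84 significant SNPs
spanning ~5.2 Mb, confirmed against up to two controls, with boundaries
extended half-way to the flanking non-significant markers. The thresholds
differ per control breed and chromosome because each is the mean of the two
calibration breeds' chromosome maxima for that comparison.

A `xpscan` command-line tool wraps the same stages
(`simulate`, `qc`, `relate`, `scan`, `ne`, `fst`, `pca`).

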