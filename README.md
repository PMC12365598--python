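# binqtl

Bin-based linkage mapping and QTL analysis for F1 pseudo-testcross
populations, with a CIELAB fruit-color scoring model.

## The problem

Dense resequencing of a biparental F1 progeny (two outbred parents, e.g. two
peach cultivars) yields tens of thousands of segregating SNPs per
chromosome.  At this density, genotyping errors and missing calls dominate
map construction: every miscalled genotype looks like a double recombination
(DR) and inflates the genetic map many-fold.  `binqtl` implements the
bin-based strategy for this regime:

1. **Filter and recode.** Biallelic sites only; markers with a missing or
   double-homozygous parental pair are dropped; offspring calls inconsistent
   with the parents are masked; markers with >20% offspring missingness or
   severe segregation distortion (f(A) > 0.9, f(A) < 0.1, or f(H) < 0.15)
   are removed.  Calls are recoded to AHB terminology (A/B homozygotes, H
   heterozygote).
2. **Pseudo-testcross split.** Markers heterozygous in exactly one parent
   segregate 1:1 and build that parent's map; markers heterozygous in both
   segregate 1:2:1 and build the combined map.
3. **Bin under the DR rule.** After automated phasing of the 1:1 sets, a
   genotype run that reverts to its flanking state is accepted as a real
   double recombination only if it is witnessed by ≥ 2 contiguous markers
   spanning ≥ 100 kb; anything smaller is a genotyping error.  Markers
   between accepted breakpoints form bins; each bin gets one consensus
   genotype per individual and is represented by its first SNP.
4. **Map.** Two-point linkage grouping (single-linkage at LOD ≥ 19),
   Kosambi distances d = 25·ln((1+2r)/(1−2r)) cM along physical order, and
   identification of possibly-IBD regions as marker-free gaps ≥ 2.5 Mb.
5. **Scan.** Haley–Knott interval mapping: phenotype regressed on expected
   QTL genotype scores from the flanking bins, LOD = (n/2)·log10(RSS0/RSS1),
   genome-wide thresholds from phenotype permutations, LOD−1 support
   intervals truncated at IBD boundaries, additive/dominance effects
   (a = (A−B)/2 for 1:2:1, A−H for 1:1; d = H−(A+B)/2) and gene-action
   classes (A/PD/D/OD) from the d/a ratio.
6. **Color scoring.** A linear model FCS = b0 + b1·L + b2·a* + b3·b* maps
   colorimeter readings to a continuous yellow-to-orange flesh-color score
   anchored on a 10-level color card (70/30 split, 5-fold CV).

A first-class synthetic-data module simulates the whole setting — Poisson
crossovers, parent-specific IBD segments, error/missingness injection, QTLs
with additive + dominance effects, graded Lab color — so every stage is
testable without any external download.

## Worked example

```python
import numpy as np
from binqtl import (SimConfig, QTLSpec, simulate_population, simulate_phenotypes,
                    filter_cascade, split_testcross, BinGenotyper, group_markers,
                    build_map, map_summary, scan_interval_mapping,
                    permutation_threshold, ScanConfig)

config = SimConfig(n_progeny=232, chrom_lengths=(25_000_000, 25_000_000),
                   marker_density=4.0, map_length_morgans=0.6,
                   marker_class_probs=(1.0, 0.0, 0.0),
                   error_rate=0.01, missing_rate=0.05, seed=42)
truth, observed = simulate_population(config)

filtered, report = filter_cascade(observed)          # masks 224 Mendelian-inconsistent calls
sf = split_testcross(filtered).sf_set                # the parent-1 (1:1) dataset

genotyper = BinGenotyper(design="BC")
onebin = genotyper.fit(sf).transform(sf)             # 199 markers -> 117 bins

groups = group_markers(onebin, lod_threshold=19.0)
gmap = build_map(onebin, groups=groups, chrom_lengths={1: 25_000_000, 2: 25_000_000})
print(map_summary(gmap, bins=genotyper.bins_).round(2))
```

```
group  n_bins  n_snps  mean_snps_per_bin     cm  coverage_pct
    1      54      94               1.74  48.11         95.14
    2      63     105               1.67  53.62         96.41
TOTAL     117     199               1.70 101.73         95.77
```

The two linkage groups recover the two simulated chromosomes; the 101.7 cM
total tracks the realized crossover count of this population (107.8
cM-equivalent — meiosis is Poisson, so a single population's realized map
differs from the 120 cM expectation).

```python
pheno = simulate_phenotypes(truth, [QTLSpec(chrom=1, pos=12_500_000, a=1.0,
                                            d=0.0, residual_sd=0.87)], seed=1)
y = pheno.set_index("individual").loc[list(truth.individuals), "value"].to_numpy()
cfg = ScanConfig(n_permutations=1000, seed=2)
profile = scan_interval_mapping(gmap, onebin, y, "BC", cfg)
threshold = permutation_threshold(gmap, onebin, y, "BC", cfg)
peak = profile.iloc[int(profile["lod"].idxmax())]
print(f"peak LOD {peak['lod']:.1f} at {peak['cm']:.1f} cM; threshold {threshold:.2f}")
```

```
peak LOD 16.3 at 16.3 cM; threshold 1.96
```

The simulated QTL (additive effect = one phenotypic sd, placed at 12.5 Mb)
is detected far above the genome-wide 5% permutation threshold, with the
peak bin at ~9.9 Mb — within the LOD−1 support interval of the truth.

Color scoring from synthetic graded Lab measurements:

```python
from binqtl import simulate_color, fit_fcs
lab = simulate_color(300, noise_sd=0.25, seed=3)
model = fit_fcs(lab, split=0.70, seed=4)
print(model.coefficients.round(3))   # [-1.843  0.007  0.039  0.151]
print(model.cv_metrics)              # r2 0.991±0.003, MAE 0.208±0.03, RMSE 0.260±0.044
```

A command-line interface covers the same workflow
(`binqtl simulate | filter | bin | map | scan | color-train | color-predict |
phenostats | exprscreen`); see `binqtl --help`.

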