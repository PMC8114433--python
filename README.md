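# echotex

Quantitative texture analysis of muscle ultrasound, for researchers who
assess muscle quality from B-mode still images.

Skeletal muscle that is infiltrated by fat and fibrous tissue looks
brighter and more *heterogeneous* on ultrasound. The classical readout,
mean echo intensity (EI — the average gray level of a region of
interest, 0 black to 255 white), is a first-order statistic: it tracks
infiltration but also tracks scanner gain, so it does not transfer
across devices or settings. Second-order texture statistics built on
the gray-level co-occurrence matrix (GLCM) describe the *spatial
arrangement* of gray levels instead, and are invariant to a constant
brightness offset.

For a displacement **d** = (Δr, Δc), the GLCM entry p(i, j) is the
probability that a pixel with gray level *i* has a neighbor at offset
**d** with gray level *j*. From p(i, j) the package computes the five
features commonly used in muscle work, each averaged over the four
distance-1 displacements [0 1], [−1 1], [−1 0], [−1 −1]:

| feature | definition | reads as |
|---|---|---|
| ASM (energy) | Σ p(i,j)² | gray-level uniformity |
| entropy | −Σ p log p | textural disorder |
| IDM (homogeneity) | Σ p/(1+(i−j)²) | similar-neighbor mass |
| contrast | Σ (i−j)² p | neighbor gray dispersion |
| correlation | cov(i,j) / norm | neighbor linear dependence |

Two correlation normalizations are exposed: the Pearson form
(σx·σy, `haralick`) and a variance-product form (σx²·σy², `walker`,
the default) matching the much smaller magnitudes produced by the
ImageJ-style texture plugin workflow this package models.

Downstream, the package implements the cohort statistics used to rank
these features against physical-function tests (incremental shuttle
walk, gait speed, timed up-and-go, 60-second sit-to-stand, handgrip):
Spearman correlation grids with pairwise deletion, Fisher-z averaging
(r → z′ = artanh r, mean, back-transform with tanh) to produce one
average coefficient per feature, Little's MCAR test,
expectation-maximization imputation under a multivariate normal model,
standardized general linear models of clinical predictors, joint-R²
variance explained, and ICC(2,1) test-retest reliability.

Because no patient images are distributable, the package ships
generators: speckle ROIs whose texture degrades with a latent
infiltration parameter, and cohorts in which texture features
(measured from the rendered pixels) and function tests share a
calibrated rank correlation, with configurable MCAR/MAR missingness.

## Worked example

```python
from echotex import ImageSimConfig, simulate_roi, averaged_features
from echotex.stats import average_correlations

healthy     = simulate_roi(ImageSimConfig(heterogeneity=0.1, seed=42))
infiltrated = simulate_roi(ImageSimConfig(heterogeneity=0.9, seed=42))
for label, roi in [("healthy", healthy), ("infiltrated", infiltrated)]:
    f = averaged_features(roi)
    print(f"{label:12s} EI={f.echo_intensity:6.1f}  ASM={f.asm:.5f}  "
          f"ENT={f.entropy:.3f}  IDM={f.idm:.3f}  CON={f.contrast:7.1f}  "
          f"COR={f.correlation:.5f}")

agg = average_correlations([-0.259, -0.275, 0.079, -0.163, -0.255])
print(f"entropy average r = {agg.r_rounded}")
```

prints

```
healthy      EI=  61.0  ASM=0.00132  ENT=6.809  IDM=0.131  CON=   76.7  COR=0.00534
infiltrated  EI=  74.2  ASM=0.00091  ENT=7.185  IDM=0.112  CON=  164.6  COR=0.00118
entropy average r = -0.177
```

The infiltrated ROI is brighter (higher EI) and more disordered:
entropy and contrast rise while ASM, IDM and correlation fall — the
signature of fat/fibrous infiltration. The last line Fisher-averages
the published entropy row of feature-by-test Spearman coefficients
into the single average coefficient (−0.177) used to rank features.

The same workflow is available from a shell:

```
echotex simulate images --out run/img --n-images 20 --seed 1
echotex extract  --manifest run/img/roi_manifest.csv --out run/feat
echotex simulate cohort --out run/coh --n-subjects 90 --seed 1
echotex analyze  --cohort run/coh/cohort.csv --out run/tables
echotex reproduce
```

Every stage writes plain CSV with a provenance header and a manifest
with SHA-256 checksums; reruns with the same seed are byte-identical.

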