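# pgcvol

Automated **pineal gland calcification (PGC) volumetry** on head CT,
**Pittsburgh Sleep Quality Index (PSQI)** scoring, and the epidemiological
association analysis that links the two — together with a synthetic-data
layer (CT phantoms with ground-truth calcification volumes, cohorts with a
planted age-confounded exposure–outcome association) so every stage can be
exercised and validated without patient data.

## Who this is for

Imaging epidemiologists studying intracranial calcification and sleep: the
pineal gland calcifies with age, calcified tissue is thought to be
hormonally inactive, and whether the calcified fraction relates to sleep
quality is an open question. The package provides the measurement
instrument (CT volumetry), the outcome instrument (PSQI scoring), and the
analysis pipeline (tertile regression, LOWESS, stratification,
interaction/mediation checks) as reproducible, testable code.

## The core computation

Given a head CT volume *V* (Hounsfield units, voxel-to-world affine *A* in
mm, RAS+ orientation) and a segmentation of the third ventricle:

1. the **ventricle centroid** c is the unweighted mean of the world
   coordinates of all labelled voxel centers;
2. the **pineal ROI center** is c − (0, 20, 0) mm — 20 mm posterior
   (RAS+: −y);
3. the **ROI** is the set of voxels whose centers lie within 12 mm of the
   ROI center (clipped at the grid boundary);
4. voxels in the ROI with attenuation **strictly > 50 HU** are calcified;
   the PGC volume is

   `volume_µL = n_calcified × |det A₃ₓ₃|`   (1 mm³ = 1 µL).

The PSQI folds 19 items into seven 0–3 components (quality, latency,
duration, efficiency, disturbances, medication, daytime dysfunction);
total 0–21, with **≥ 6 classifying a poor sleeper**. The cohort analysis
rounds PGC volumes to integer µL, splits them at the empirical tertiles
(ties grouped down), and fits Gaussian and logistic GLMs of the PSQI total
and the poor-sleep class on tertile indicators, unadjusted and adjusted
for age and sex, with Wald 95% CIs.

## Worked example

```python
import pgcvol as pv

# a synthetic scan with known truth: one 2.5 mm calcified blob
vol, mask, truth = pv.make_phantom(pv.PhantomSpec(noise_sd_HU=0.0))
res = pv.measure_pgc(vol, mask)
print(res.volume_uL, truth.true_voxelized_volume_uL)
# 64.827 64.827        <- exact recovery on a noiseless phantom

# a synthetic cohort calibrated to a middle-aged/older population
cohort = pv.make_cohort(pv.CohortSpec(n=1009, seed=1))
tert = pv.assign_tertiles(cohort["pgc_uL"])
print(tert.cutpoints, tert.counts)
# (20, 57) (337, 344, 328)   <- integer-µL tertile boundaries and sizes

fit = pv.fit_psqi_glm(cohort, tert, adjust=False)
adj = pv.fit_psqi_glm(cohort, tert, adjust=True)
print(round(fit.terms["tertile_2"].beta, 3), round(adj.terms["tertile_2"].beta, 3))
# 0.706 0.506   <- the crude tertile effect attenuates once age and sex
#                  enter the model, the signature of age confounding
```

The numbers printed above are what the code produces for those seeds: the
phantom volume is recovered to the voxel, and the planted age-confounded
association shrinks under adjustment, as it should.

Command line (same pipeline end to end, deterministic per seed):

```sh
pgc demo --out report/ --seed 7     # phantom -> measure -> cohort -> analyze
pgc measure --ct ct.nii.gz --mask seg.nii.gz --label 1 --out result.csv
pgc psqi --items items.csv --out scored.csv
pgc analyze --cohort cohort.csv --out report/
```

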