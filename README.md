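# vatmap

Connectomic overlay analysis for deep brain stimulation (DBS): given electrode
contact positions, stimulation currents and clinical outcomes, `vatmap` asks
*which white-matter structure's stimulation explains the clinical response?*
— and answers it with a deliberately simple, fully testable pipeline.

It is written for researchers analysing DBS cohorts against streamline
atlases or normative connectomes (the motivating use case is DBS for
treatment-resistant obsessive-compulsive disorder, with outcome measured as
relative Y-BOCS reduction), and for methodologists who want every stage of
such an analysis exercised against independent oracles on synthetic data.

## The model

**Volume of activated tissue (VAT).** Each patient-hemisphere's active
contacts are reduced to their geometric center, and the stimulated volume is
a sphere whose radius follows Coulomb's law for a point current source in a
homogeneous medium:

    r = sqrt( I / (4 π σ E) )

with current *I* (mA), tissue conductivity σ = 0.1 S/m and activation
threshold E = 0.2 V/mm by default (so I = 1 mA gives r ≈ 1.99 mm, and
quadrupling the current doubles the radius).

**Streamline density and activation score.** A bundle is rendered onto an
isotropic grid by visitation counting (resampling at half the voxel size)
and smoothed with a Gaussian kernel (σ in mm). The *activation* of the
bundle at a site is the mean of this density image over all voxels whose
centers fall inside the VAT sphere.

**Statistics.** Improvement (relative score reduction, (baseline −
follow-up)/baseline) is regressed on activation by univariate OLS, pooling
left and right hemispheres as separate observations; reported are the slope
p-value and adjusted R². Predictive value is the leave-one-out 1 − R²: the
mean squared out-of-sample error normalized by the whole-group outcome
variance — its complement may be negative.

**Cortical fingerprints.** Streamlines are selected from a normative
tractogram by small spherical ROIs around the stimulation coordinates; the
selection's endpoint ("terminal") density, smoothed on a 1 mm grid, is the
group's cortical fingerprint. Local maxima give peak penetration
coordinates, and peaks of two groups that fall within a pairing distance
inside the joint supra-threshold mask are reported as *conjugation regions*
— cortex addressed by both targets.

Because the patient imaging and atlases such analyses run on are not
redistributable, the package ships a first-class synthetic generator
(`vatmap.synthetic_data`): smooth fiber bundles around parametric
centerlines, bilateral cohorts with jittered contact placement and
truncated-normal currents/baselines, and outcomes linear in a chosen
bundle's activation.

## Worked example

`analysis/` holds the numbered drivers of the full synthetic study. The
screen step (`python analysis/02_activation_screen.py 1`) generates three
bundles — a true bundle and two disjoint decoys — and 26 bilateral patients
whose improvement is linear in true-bundle activation (noise calibrated to a
patient-level R² of ~0.5), then prints the structure screen:

```
structure partition  n   slope      p  r2_adj  r2_loo
 bundle_S     joint 52  0.0617 0.0125  0.1009  0.0494
  decoy_B     joint 52 -1.6856 0.4308 -0.0073 -1.5869
  decoy_A     joint 52 -4.5545 0.5888 -0.0140 -0.0389

top structure by joint adjusted R²: bundle_S (r2_adj=0.101, p=1.25e-02, r2_loo=0.049)
```

The true bundle is the only structure with a significant slope and the top
adjusted R²; the decoys sit at chance, and their leave-one-out R² goes
negative — predicting worse than the group mean, exactly what a null
structure should do. (The joint hemisphere-pooled R² is lower than the
patient-level 0.5 because each hemisphere's activation is a noisy proxy for
the bilateral mean that generated the outcome.)

`python analysis/03_fingerprints.py 1` runs the fingerprint stage on a
synthetic connectome with one shared and two exclusive cortical endpoint
blobs and reports exactly one conjugation, at the planted shared blob:

```
conjugations: 1
  A(0.0, 0.0, 40.0) <-> B(0.0, 0.0, 40.0)  (distance to planted shared blob: 0.0 mm)
```

The same pipeline is scriptable via the `vatmap` CLI (`simulate`, `score`,
`regress`, `fingerprint`, `run-all`) with a YAML config, and every stage is
importable from the library for real (TRK/TCK + NIfTI + CSV) inputs.

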