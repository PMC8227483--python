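# perfdose

Patient-specific organ and effective dose estimation for dynamic CT
myocardial-perfusion (CT-MPI) examinations, as a reusable, tested Python
pipeline.

A dynamic perfusion scan of the heart delivers a non-trivial radiation dose
(tens of mGy to in-beam organs), but the acquired CT volume covers only
~7 cm of the thorax, so dose metrics computed from the scan data alone miss
the scattered dose to the rest of the body. `perfdose` implements the full
estimation chain for a dual-source scanner in shuttle mode:

1. **Harmonisation** — remove the patient support table, resample patient
   and whole-body reference voxel phantom to a common grid
   (nearest-neighbour), rescale the phantom so body cross-sections agree at
   the junction (f = √(A_patient/A_phantom)), splice the patient block into
   the phantom, re-insert the table and optionally append truncated
   peripheral adipose as a circle segment.
2. **Material conversion** — map HU to materials via an ordered bin table;
   between 200 HU and the case-specific maximum blood HU, 50-HU-wide
   blood–iodine bins carry mixtures with iodine concentration
   c = (HU_mid − 40)/k mg/ml (k = 41.12 at 80 kV, 31.74 at 100 kV), read as
   an iodine mass percentage of c/10.
3. **Monte Carlo transport** — a calibrated CT source model (spectrum,
   Al-equivalent bowtie, helical dual-tube fan-beam geometry, measured
   free-in-air kerma at the isocenter) drives Woodcock (delta-tracking)
   photon transport with Klein–Nishina scattering on the voxel grid; tube A
   and B dose maps are summed and scaled by the 95/360 shuttle arc and the
   15 time points.
4. **Reporting** — organ mean doses over segmentation masks, the red bone
   marrow dose via the mass energy-absorption coefficient ratio method
   (D_rbm = (μ_en/ρ)_rbm/(μ_en/ρ)_bone · D_bone, combined with the phantom
   spongiosa region), the phantom fallback for lymphatic nodes, the
   ICRP-103 effective dose E = Σᵢ wᵢ·Dᵢ, and cohort summaries with the
   ≤32 cm / >32 cm effective-diameter protocol split.

A first-class synthetic-data module generates miniature patient-like thorax
volumes and a whole-body reference phantom with exact analytic ground
truth, so the entire chain is testable without any external data.

## Worked example

`examples/03_simulate_dose.py` runs one synthetic case end-to-end
(100 000 photons per tube, 80 kV / 370 mAs shuttle protocol):

```
case example: 80 kV, blood max 500 HU, phantom scale factor 1.041
organ              mean dose (mGy)
  heart               94.82
  bones               67.43
  lungs               62.69
  breasts             60.63
  oesophagus          24.16
  rbm                 18.06
  thymus               9.01
  muscle               6.26
effective dose: 20.08 mSv (ICRP-103 weighted sum; miniature-anatomy scale, not clinical)
```

The heart (directly in the beam, with the iodine-enhanced blood pool)
receives the highest mean dose, followed by lungs and breasts; organs
outside the ~73 mm scan range see only scattered dose. The absolute values
reflect the miniature synthetic anatomy — less tissue attenuates and more
of each organ lies in-beam than in an adult — so they are larger than
clinical per-case values; the orderings and the 100 kV > 80 kV contrast are
the physically meaningful outputs. `examples/04_cohort_summary.py`
reproduces the published cohort statistics from the packaged 20-case
reference cohort:

```
80 kV: mean effective dose (all 20 cases) = 7.5 mSv
  le32cm: 8.2 +/- 2.1 mSv (n=13)
  gt32cm: 6.3 +/- 1.3 mSv (n=7)
100 kV vs 80 kV, all cases: +75%
protocol-matched groups: +36%  (combined mean 9.2 mSv)
```

The other examples cover synthetic-case generation (`01`) and the
blood–iodine material table (`02`).

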