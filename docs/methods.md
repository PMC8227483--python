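# Methods

`perfdose` implements a patient-specific dosimetry procedure for dynamic CT
myocardial-perfusion (CT-MPI) examinations on a dual-source scanner operated
in shuttle mode. The input is a contrast-enhanced thorax CT volume; because
such a volume covers only part of the body, it is merged with a whole-body
reference voxel phantom before simulation so that scattered dose to organs
outside the scan range is represented. The output is a per-case report of
mean organ absorbed doses (mGy) and the ICRP-103 effective dose (mSv).

## Harmonisation (patient-phantom matching)

The preprocessing chain runs in a fixed order: (1) the patient support table
is removed (set to air); (2) patient and phantom are resampled to a common
grid by nearest-neighbour interpolation (configurable; 0.98 mm in-plane and
3 mm slices mirror the clinical data, the synthetic pipeline defaults to
2 mm / 4 mm); (3) corresponding junction slices are identified (a config
input — a helper suggests candidates from body-area profiles but never
auto-commits); (4) the phantom is rescaled in-plane about its body centroid
by f = sqrt(A_patient / A_phantom), the factor measured at the lower
junction; any residual mismatch at the upper junction is logged, not
corrected; (5) the patient block replaces the corresponding phantom slices,
with a provenance volume recording the origin of every voxel; (6) the table
is re-inserted at a configurable 100 HU (carbon-fibre-like; treated as soft
tissue by the material table); (7) peripheral adipose truncated by a small
reconstruction field of view can be appended as a circle segment per axial
slice (explicit opt-in; the segment is defined by a chord fraction of the
body's lateral extent and a maximum thickness).

Patient size is summarised by the maximum effective diameter
sqrt(LAT x AP), measured slice-by-slice on the largest connected component
of the -300 HU body contour (bounding-box extents; the contour rule is a
package choice).

## HU-to-material conversion

The phantom is converted to phantom-based HU (air -1000, lung -700, adipose
-100, soft tissue 30, blood 200, bone 1000; all bone compartments map to
bone; a contrast variant raises blood to 500 HU). The merged HU volume maps
onto an ordered material table: air -1024..-900, lung -899..-300, adipose
-299..-50, muscle -49..199, blood-iodine bins of 50 HU from 200 up to the
case's maximum blood HU, bone up to 1999, iron 2000..64535. The maximum
blood HU follows three rules applied to the blood-voxel HU sample: the 90th
percentile if more than 10% of blood exceeds 501 HU, else the maximum if it
is below 501 HU, else 499 HU. A trailing remainder bin shorter than 20 HU
merges into the previous bin, which reproduces the published per-case bin
layouts (e.g. 450..510 for a 510 HU maximum but a separate 750..771 bin for
771).

Each blood-iodine bin carries a mixture whose iodine concentration follows
the linear enhancement relation c = (HU_mid - 40)/k with k = 41.12 (80 kV)
or 31.74 (100 kV) HU/(mg/ml); c mg/ml is read as c mg per 1000 mg of
mixture, i.e. an iodine mass percentage of c/10, with the rest blood. This
convention regenerates 21 of the 24 published mixture percentages at the
printed precision; the three non-conforming entries (80 kV mixture 1,
100 kV mixtures 10 and 12) deviate from the midpoint formula by +0.007,
-0.061 and -0.126 percentage points and are asserted as known deltas.
Mixtures inherit the blood density (1.06 g/cm3); the mass-fraction
convention is independent of that choice.

## Source model and calibration

The scan protocol encodes the printed constants of the 80 kV / 370 mAs and
100 kV / 300 mAs CT-MPI protocols: focus-isocenter distance 595 mm, beam
collimation 38.4 mm, table increment 34.56 mm per rotation (pitch 0.9), fan
angles 0.7955 rad (tube A) and 0.5441 rad (tube B), 36 projections per
rotation, a 95/360 shuttle arc fraction, 15 time points, and measured
free-in-air kerma constants 5.66 and 10.35 mGy/100 mAs at the isocenter.

Photon emission samples a continuous-uniform gantry angle over two full
rotations (start-angle averaging; a 36-discrete-projections mode exists
behind a flag), a uniform fan angle within the tube's half fan angle, and a
uniform cone offset covering the collimation at the isocenter. The focus
advances one table increment over the simulated angular range, making the
imaged length increment + collimation ≈ 73 mm. Energies are drawn from the
tube spectrum hardened by the fan-angle-dependent Al-equivalent bowtie
thickness (32 fan strata). The packaged spectra are synthetic tungsten
models (Kramers continuum, W K lines, 6.5 mm Al inherent filtration chosen
from typical CT half-value layers) and the packaged bowtie profiles are
smooth synthetic shapes; both are labelled `_synthetic` and documented in
`data/provenance.md`. The 80 kV bowtie shape is used for both voltages.

Absolute dose comes from a closed-form free-in-air kerma per simulated
photon at the isocenter (centre-ray filtered spectrum, emission-sampler
solid-angle normalisation, no scatter, air attenuation neglected); the
calibration scale is (k_meas_per_100mAs x mAs/100) / (k_sim_per_photon x N).
Because the collimation is defined at the isocenter, this kerma scales as
1/R with the focus distance (the emitted solid angle shrinks with R);
inverse-square falloff inside a fixed geometry is verified in the transport
tests.

## Photon transport

Woodcock (delta) tracking against a per-energy majorant over the materials
present in the volume; 1 keV cross-section bins over 1-150 keV. Interaction
channels: photoelectric absorption (full local deposit), incoherent scatter
with exact free-electron Klein-Nishina rejection sampling (local deposit of
the electron energy: kerma approximation, no electron transport — adequate
for CT energies and mm-scale voxels), and coherent scatter (on by default)
with a Thomson angular shape and a screened-form-factor magnitude.
Characteristic fluorescence (including iodine K at ~33 keV) is not
re-emitted in transport; its escape is accounted for only in the mu_en
tables, which slightly overestimates local absorption in iodine-rich and
iron voxels. Histories terminate below a 10 keV cutoff (local deposit), at
a 10-interaction cap (the remaining energy is deposited locally — a
conservation-preserving reading of the cap), or on exit; deposited plus
escaped energy equals emitted energy to better than 1e-9 relative. Voxel
mass uses the nominal bin density (not HU-scaled). Dose grids from tubes A
and B are summed and multiplied by the 95/360 arc fraction and the 15 time
points. Reproducibility is exact for a fixed seed; per-voxel relative
uncertainties are available from batch statistics.

An independent analog ray-trace sampler (explicit per-voxel boundary
crossings and exponential path sampling, sharing no tracking logic with the
kernel) serves as a cross-check on mean dose in heterogeneous slabs.

## Dose reduction and effective dose

Organ doses are means of the dose grid over organ masks (region-of-interest
∧ HU-window segmentation for patient data; label reuse for the phantom
part). Red bone marrow cannot be segmented from CT: the patient-region bone
dose is converted with the spectrum-weighted MEAC ratio
(mu_en/rho)_rbm / (mu_en/rho)_bone and combined with the phantom-region
spongiosa dose in a voxel-count-weighted mean, with the patient bone count
multiplied by the phantom's spongiosa/bone count ratio. "Bone" here is the
homogenised whole skeleton (cortical + trabecular bone with red and yellow
marrow, mass-weighted 0.597/0.134/0.269 per adult-female reference masses).
With the packaged spectra the computed ratios are 0.2162 (80 kV) and 0.2312
(100 kV); the corresponding published constants are 0.2761 and 0.3014,
which would require either a much harder incident spectrum (mean ≈ 59 keV
at 80 kV) or a bone mixture with ~42% mineral mass — neither of which we
can justify independently, so the package uses its computed ratio and the
acceptance comparison against the published constants is reported as a
known discrepancy rather than tuned away. Users can pass the published
constants explicitly to `rbm_dose`.

Lymphatic nodes cannot be segmented from patient data; the phantom-only
value is applied to every case at the same tube voltage (`lymph_fallback`),
or, in the synthetic pipeline, taken from the phantom-provenance region of
the merged volume. Effective dose is E = sum_i w_i D_i with ICRP-103
weights, the female remainder list (13 tissues, arithmetic-mean remainder
dose), the "bones" dose standing in for bone surface, and 1 mGy = 1 mSv for
photons. Cohort summaries report means and sample (n-1) standard
deviations per group, group contrasts as percentage differences of means,
and the ≤32 cm / >32 cm effective-diameter protocol split.

## Synthetic data

The generator provides miniature stand-ins with exact analytic ground
truth: all organs are ellipsoids/cylinders voxelised by centre-of-voxel
inclusion and clipped to the torso. The patient-like volume (default
96x96x32 at 2x2x3 mm, torso semi-axes 80x60 mm) contains lungs, a heart
with an enhanced blood pool (default 500 HU, the value used for
phantom-data contrast simulation; optionally a linear HU ramp to exercise
multi-bin iodine tables), breasts, spine with a spongiosa core, ribs, an
oesophagus, a circular-arc table, additive Gaussian HU noise (default 5 HU,
clipped to [-1024, 3071]) and optional lateral adipose truncation. The
reference phantom (default 120x100x110 at 1.775x1.775x4.84 mm, the
reference-phantom voxel dimensions) spans head to thigh and carries every
ICRP-103 organ, with out-of-thorax organs as small token regions in
anatomical z-order so scatter falloff with distance is testable; the
outermost body voxel layer is skin. Grid sizes and the desk-scale photon
budgets (default 1e5, acceptance 1.5e5 per tube; the clinical-scale
simulations used orders of magnitude more) are package choices that keep
statistical noise in in-beam organs at the few-percent level.

What passing synthetic tests do not show: real CT noise texture,
reconstruction and beam-hardening artefacts, anatomically realistic organ
shapes and HU overlap between enhanced blood and bone, or absolute dose
accuracy against measurements — those require the real phantom and
validation data.

## Numerical choices

Nearest-neighbour resampling maps each target voxel centre to the closest
source centre with ties toward the lower index. Material bins are inclusive
on both ends as printed; where published bin edges overlap, the blood bin
wins and bone starts one HU above the blood maximum. MEAC spectral sums use
cubic-spline interpolation of log-coefficients at 1 keV steps and treat the
spectral weight R_E as the normalised fluence of the spectrum as given.
Degenerate inputs raise: empty blood samples, empty organ masks (callers
must fall back to the phantom), junction indices outside the volumes, scale
factors outside [0.5, 2.0].
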