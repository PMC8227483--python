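"""Run one synthetic CT-MPI case end-to-end and print the dose report.

Generates the synthetic patient + phantom, harmonises them, builds the
material table, runs the two-tube Monte Carlo simulation with the 80 kV /
370 mAs shuttle protocol (95/360 arc, 15 time points) and reduces the dose
grid to organ doses and an ICRP-103 effective dose.  The photon budget is
desk-scale; in-beam organ doses carry a few percent statistical noise.
"""

from perfdose import mc_transport as mc
from perfdose import pipeline as pl
from perfdose import synthetic_data as sd

cfg = pl.CaseConfig(
    case_id="example",
    protocol="flash80",
    patient_spec=sd.SyntheticPhantomSpec(noise_sd=0.0, seed=1),
    transport=mc.TransportConfig(n_photons=100_000, seed=1),
)
report, artifacts = pl.run_case(cfg)

print(f"case {report.case_id}: {report.kv} kV, "
      f"blood max {report.meta['blood_max_hu']} HU, "
      f"phantom scale factor {report.meta['scale_factor']:.3f}")
print(f"{'organ':<18s} mean dose (mGy)")
for organ in sorted(report.doses, key=report.doses.get, reverse=True)[:8]:
    print(f"  {organ:<16s} {report.doses[organ]:8.2f}")
print(f"effective dose: {report.effective_dose_msv:.2f} mSv "
      f"(ICRP-103 weighted sum; miniature-anatomy scale, not clinical)")
# in-beam organs (heart, then lungs/breasts) dominate; organs outside the
# ~73 mm scan range receive only scattered dose, falling off with distance
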