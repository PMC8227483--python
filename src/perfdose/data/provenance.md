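# Package data provenance

- `element_coefficients.tsv` — elemental photon mass-attenuation (mu/rho) and
  mass energy-absorption (mu_en/rho) coefficients, 1-150 keV, for H, C, N, O,
  Na, Mg, Al, P, S, Cl, Ar, K, Ca, Fe and I. Generated deterministically by
  `scripts/make_element_tables.py` from an analytic cross-section model:
  exact free-electron Klein-Nishina incoherent scattering, screened-form-factor
  coherent scattering (single screening constant calibrated on water), and a
  photoelectric residual anchored to standard total-attenuation compilation
  values at 10-150 keV (plus the iodine K edge), with K-fluorescence escape
  corrections. Composite water values agree with standard reference data to
  within 0.1% (mu/rho) and ~2% (mu_en/rho) over 20-150 keV. Sub-10 keV rows
  are smooth extrapolations and are below the transport cutoff.
- `compositions.yaml` — elemental mass fractions and densities of the body
  tissues (ICRU-44 adult reference tissues), the adult-female phantom
  spongiosa, a homogenised whole-skeleton bone, water, iodine, iron and
  aluminium.
- `spectrum_80kv_synthetic.txt`, `spectrum_100kv_synthetic.txt` — synthetic
  tungsten-anode spectra (Kramers continuum + W K lines, 6.5 mm Al inherent
  filtration), generated by `scripts/make_spectra.py`. Stand-ins for the
  scanner's measured spectra, which are not publicly available.
- `bowtie_tubeA_80kv_synthetic.txt`, `bowtie_tubeB_80kv_synthetic.txt` —
  synthetic Al-equivalent bowtie profiles (smooth even polynomials, zero at
  the centre, additional to the inherent filtration already in the spectra).
  Stand-ins for the measured profiles. The 80 kV shape is used for both tube
  voltages.
- `icrp103_female_weights.yaml` — ICRP Publication 103 tissue weighting
  factors with the female remainder organ list.
- `reference_cohort_80kv.tsv`, `reference_cohort_100kv.tsv`,
  `reference_cohort_diameters.tsv` — published per-case organ absorbed doses,
  effective doses and maximum effective diameters of a 20-patient dynamic
  CT myocardial-perfusion cohort (plus the reference-phantom row), transcribed
  as the fixture for the cohort-statistics checks.
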