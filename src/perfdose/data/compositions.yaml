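# Elemental mass fractions and nominal densities (g/cm^3) of the materials
# used by the HU-to-material conversion and the dosimetry post-processing.
# Tissue compositions follow the ICRU-44 adult reference tissues; spongiosa
# follows the adult-female reference voxel phantom media; whole_bone is the
# homogenised skeleton (mineral bone + marrow, mass-weighted with adult-female
# reference masses: cortical+trabecular 0.597, red marrow 0.134, yellow
# marrow 0.269) used wherever "bone including all compositional structures"
# is meant.
air:
  density: 0.0012
  fractions: {C: 0.000124, N: 0.755267, O: 0.231781, Ar: 0.012827}
lung:
  density: 0.26
  fractions: {H: 0.103, C: 0.105, N: 0.031, O: 0.749, Na: 0.002, P: 0.002,
              S: 0.003, Cl: 0.003, K: 0.002}
adipose:
  density: 0.95
  fractions: {H: 0.114, C: 0.598, N: 0.007, O: 0.278, Na: 0.001, S: 0.001,
              Cl: 0.001}
muscle:
  density: 1.05
  fractions: {H: 0.102, C: 0.143, N: 0.034, O: 0.710, Na: 0.001, P: 0.002,
              S: 0.003, Cl: 0.001, K: 0.004}
blood:
  density: 1.06
  fractions: {H: 0.102, C: 0.110, N: 0.033, O: 0.745, Na: 0.001, P: 0.001,
              S: 0.002, Cl: 0.003, K: 0.002, Fe: 0.001}
cortical_bone:
  density: 1.92
  fractions: {H: 0.034, C: 0.155, N: 0.042, O: 0.435, Na: 0.001, Mg: 0.002,
              P: 0.103, S: 0.003, Ca: 0.225}
red_marrow:
  density: 1.03
  fractions: {H: 0.105, C: 0.414, N: 0.034, O: 0.439, P: 0.001, S: 0.002,
              Cl: 0.002, K: 0.002, Fe: 0.001}
yellow_marrow:
  density: 0.98
  fractions: {H: 0.115, C: 0.644, N: 0.007, O: 0.231, Na: 0.001, S: 0.001,
              Cl: 0.001}
spongiosa:
  density: 1.18
  fractions: {H: 0.085, C: 0.404, N: 0.058, O: 0.367, Na: 0.001, Mg: 0.001,
              P: 0.034, S: 0.002, Cl: 0.002, K: 0.001, Ca: 0.044, Fe: 0.001}
whole_bone:
  density: 1.55
  fractions: {H: 0.065310, C: 0.321247, N: 0.031513, O: 0.380660,
              Na: 0.000866, Mg: 0.001194, P: 0.061625, S: 0.002328,
              Cl: 0.000537, K: 0.000268, Ca: 0.134318, Fe: 0.000134}
water:
  density: 1.0
  fractions: {H: 0.1119, O: 0.8881}
iodine:
  density: 4.93
  fractions: {I: 1.0}
iron:
  density: 7.874
  fractions: {Fe: 1.0}
aluminium:
  density: 2.699
  fractions: {Al: 1.0}
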