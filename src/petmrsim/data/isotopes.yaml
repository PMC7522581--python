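# Beta-plus decay schemes for the supported PET isotopes.
#
# Fields per isotope:
#   daughter_z       : atomic number of the daughter nucleus (enters the
#                      Coulomb correction of the beta spectrum)
#   branching_ratio  : total beta-plus fraction of all decays, percent
#   branches         : list of beta-plus branches; intensities are fractions
#                      of ALL decays and sum to branching_ratio/100.
#     endpoint_kev   : maximum positron kinetic energy of the branch
#     intensity      : fraction of all decays taking this branch
#     prompt_gamma_kev : de-excitation gamma emitted in coincidence with
#                      this branch (omit if none)
#
# 82Rb: 13.1% of beta decays feed an excited state (2604 keV endpoint) and are
# accompanied by a 777 keV prompt gamma.  68Ga: 1.2% of beta decays take a
# gamma-coincident branch; the gamma energy is the 1077 keV 68Zn line.
F18:
  daughter_z: 8
  branching_ratio: 96.76
  branches:
    - endpoint_kev: 633.5
      intensity: 0.9676
O15:
  daughter_z: 7
  branching_ratio: 99.89
  branches:
    - endpoint_kev: 1732.0
      intensity: 0.9989
N13:
  daughter_z: 6
  branching_ratio: 99.82
  branches:
    - endpoint_kev: 1198.5
      intensity: 0.9982
C11:
  daughter_z: 5
  branching_ratio: 99.75
  branches:
    - endpoint_kev: 960.2
      intensity: 0.9975
Ga68:
  daughter_z: 30
  branching_ratio: 87.90
  branches:
    - endpoint_kev: 1899.0
      intensity: 0.868452
    - endpoint_kev: 1883.0
      intensity: 0.010548
      prompt_gamma_kev: 1077.0
Rb82:
  daughter_z: 36
  branching_ratio: 95.45
  branches:
    - endpoint_kev: 3378.0
      intensity: 0.8294605
    - endpoint_kev: 2604.0
      intensity: 0.1250395
      prompt_gamma_kev: 777.0
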