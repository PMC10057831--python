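# Plasma-phase and clot-phase kinetic / pharmacokinetic constants for the four
# plasminogen activators, transcribed from published in vitro and clinical values.
# Internal units: concentrations in uM, time in seconds, Vc_per_kg in L/kg.
#
# These numbers are a literal transcription of the published parameter tables and
# are NOT part of the calibration surface (see calibration.yaml for everything
# that is). Do not tune them.
#
# Notes on units:
#   - C0 is printed in nM in the source tables; stored here in uM.
#   - kPAI is treated as uM^-1 s^-1 for every drug (one source column prints
#     "uM^-1" for urokinase; see docs/methods.md).
#   - clot-phase KM/kcat assumed uM and s^-1 throughout.
schema_version: 1
drugs:
  alteplase:
    C0: 5.0e-5            # 0.05 nM endogenous tPA
    KM_plasma: 28.0
    kcat_plasma: 0.3
    kPAI: 37.0
    kel: 2.27e-3
    kcp: 3.1e-4
    kpc: 3.34e-4
    Vc_per_kg: 0.057
    ka: 0.01              # uM^-1 s^-1, fibrin adsorption
    kd_off: 0.0058        # s^-1 (Kd = kd_off/ka = 0.58 uM)
    KM_clot: 0.16
    kcat_clot: 0.3
    fibrin_binding: true
    endogenous_secretion: true
  tenecteplase:
    C0: 0.0
    KM_plasma: 20.0
    kcat_plasma: 0.04
    kPAI: 0.15
    kel: 3.89e-4
    kcp: 1.1e-4
    kpc: 1.37e-4
    Vc_per_kg: 0.0496
    ka: 0.01
    kd_off: 0.0015        # Kd = 0.15 uM
    KM_clot: 2.8
    kcat_clot: 0.54
    fibrin_binding: true
    endogenous_secretion: false
  reteplase:
    C0: 0.0
    KM_plasma: 0.2
    kcat_plasma: 3.3e-4
    kPAI: 37.0
    kel: 8.33e-4
    kcp: 1.82e-4
    kpc: 1.53e-4
    Vc_per_kg: 0.25
    ka: 0.01
    kd_off: 0.011         # Kd = 1.1 uM
    KM_clot: 4.6
    kcat_clot: 0.32
    fibrin_binding: true
    endogenous_secretion: false
  urokinase:
    C0: 7.0e-4            # 0.7 nM endogenous uPA
    KM_plasma: 50.0
    kcat_plasma: 1.0
    kPAI: 160.0
    kel: 4.06e-4
    kcp: 4.39e-4
    kpc: 1.28e-4
    Vc_per_kg: 0.13
    ka: 0.0               # uPA has no fibrin affinity
    kd_off: 0.0
    KM_clot: 0.81
    kcat_clot: 2.6
    fibrin_binding: false
    endogenous_secretion: true
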