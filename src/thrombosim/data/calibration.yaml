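# ============================ CALIBRATION SURFACE ============================
# Every constant in this file is NOT printed in the drug parameter tables: the
# source model family defers them to its antecedent studies, or they are generic
# physiological quantities. They are collected here so that they are auditable
# and swappable without touching code. Default-scenario behaviour (lysis times,
# activation times, fibrinogen depletion) is calibrated through THIS FILE ONLY.
#
# Units: concentrations uM, time s, lengths m, pressure Pa, viscosity Pa s,
# diffusivity m^2/s, molecular weight g/mol, second-order rates uM^-1 s^-1.
# =============================================================================
schema_version: 1

# Molecular weights used for the mg -> uM dose conversion. Urokinase is the
# low-molecular-weight therapeutic form.
molecular_weights:
  alteplase: 59050.0
  tenecteplase: 58951.0
  reteplase: 39571.0
  urokinase: 33000.0

# Baseline plasma concentrations and first-order turnover of the six
# fibrinolytic proteins. Secretion is derived as S_i = kel_i * C_init
# (homeostatic drug-free steady state).
proteins:
  PLG: {C_init: 2.2,    kel: 5.0e-6}    # plasminogen ~2.2 uM, half-life ~2 d
  PLS: {C_init: 0.0,    kel: 1.0e-4}    # no free plasmin at rest
  AP:  {C_init: 1.0,    kel: 5.0e-6}    # alpha2-antiplasmin ~1 uM
  MG:  {C_init: 3.0,    kel: 5.0e-6}    # alpha2-macroglobulin ~3 uM
  FBG: {C_init: 8.0,    kel: 5.0e-6}    # fibrinogen ~2.7 g/L / 340 kDa
  PAI: {C_init: 4.0e-4, kel: 2.0e-4}    # active PAI-1 ~0.4 nM; functional decay
                                        # (latency conversion) half-life ~1 h

# Plasma-phase second-order rate constants for the reactions the drug tables
# do not cover: plasmin inhibition by AP and MG, and fibrinogen degradation by
# plasmin (catalytic in plasmin).
plasma_kinetics:
  k_pls_ap: 10.0      # PLS + AP -> inactive
  k_pls_mg: 0.1       # PLS + MG -> inactive
  k_pls_fbg: 0.1      # PLS + FBG -> degradation products (PLS catalytic)

# Clot geometry, porous-medium transport, and fibrin binding-site model.
clot:
  L_clot: 0.01            # 10 mm occlusion
  n_cells: 50
  entry_length: 0.0       # clot-free entry region upstream of the clot face
  epsilon_clot: 0.75
  fiber_radius: 2.0e-7    # 200 nm fibrin fiber radius (coarse clot)
  n_total_init: 1.0       # accessible fibrin binding-site concentration
  dp_per_length: 4.6e+5   # pressure gradient across the occlusion (~35 mmHg/cm)
  mu: 1.3e-3              # plasma dynamic viscosity (cells do not enter pores)
  D: 5.0e-11              # free-species diffusivity in the clot (all species)
  kdeg: 6.25e-2           # lysis coefficient
  gamma: 10.0             # plasmin cuts to degrade one fibrin unit
  x_monitor: 0.005        # activation-time monitoring position (5 mm)
  pressure_mode: per_length  # gradient held across the intact clot
  u_max: 0.02             # m/s, numerical velocity cap after recanalization
  spin_up: 0.0            # s, drug-free pre-dose equilibration (no-op default)
  # Fibrin binding of plasminogen and plasmin (the activator's ka/kd come from
  # the drug tables). Plasminogen binds intact fibrin weakly (Kd 20 uM);
  # plasmin binds tightly through its kringle domains (Kd 0.5 uM).
  plg_binding: {ka: 0.005, kd: 0.1}
  pls_binding: {ka: 0.04, kd: 0.02}
  bound_plasmin_protected: true        # AP/MG act only on free-phase plasmin
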