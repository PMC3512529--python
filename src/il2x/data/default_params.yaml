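# il2x default parameter set, version 1.
#
# Calibrated so that, for the shipped model, the resting receptor number is
# g_c/a_U = 150, the single-cell commitment threshold is m_c ~ 0.5, and the
# critical competition window for (m1 = 0.65, m2 = 1) is ~14 h.
# See docs/methods.md for the calibration procedure and rationale.
#
# Units are fixed package-wide: time in minutes, amounts in molecule counts,
# volume in cubic microns. k_on is given per molar per minute and is converted
# internally to a per-molecule rate 1/(N_A * V).
version: 1
units:
  time: minute
  amount: molecules
  volume: um^3
cell:
  m: 1.0                    # TCR signal strength, dimensionless in [0, 1]
  g_c: 0.0510204            # constitutive IL-2R synthesis, molecules/min
  a_U: 3.40136e-4           # unbound IL-2R internalization, 1/min (g_c/a_U = 150)
  a_B: 3.40136e-4           # bound-complex internalization, 1/min
  feedback:
    form: hill
    g_f: 6.12245            # maximal induced synthesis rate, molecules/min
    K_f: 800.0              # half-saturation bound-receptor count, molecules
    n: 2.0                  # Hill coefficient
  secretion:
    mode: proportional_to_m
    s: 0.670068             # maximal IL-2 secretion rate, molecules/min
medium:
  volume: 100.0             # interaction volume, um^3 (two-cell setting)
  d_I: 4.0                  # free IL-2 removal (degradation/transport), 1/min
  k_on: 6.6e8               # IL-2/IL-2R association, 1/(M min)  (~1.1e7 /M/s)
  k_off: 4.4898e-4          # dissociation, 1/min  (K_d = 10 pM)
  external_source: 0.0      # exogenous IL-2 entering the volume, molecules/min
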