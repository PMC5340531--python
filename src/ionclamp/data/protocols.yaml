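# Voltage-clamp protocol parameter table, version 1.
#
# Times in ms, voltages in mV.  TA/TB delimit the analysis window used for
# feature extraction.  Stepped protocols grade one segment between the listed
# bounds in increments of dV (both endpoints included):
#   activation:   hold V0 (T1) | step V in [V1..V2] (T2) | hold V0 (T3)
#   inactivation: hold V0 (T1) | prepulse V in [V1..V2] (T2) | test V3 (T3) | hold V0 (T4)
#   deactivation: hold V0 (T1) | step V1 (T2) | tail V in [V2..V3] (T3) | hold V0 (T4)
#   ramp:         hold V0 (T1) | eight alternating linear ramps V0<->V1 with
#                 durations T2..T9, starting upward (four up/down pairs)
#   action_potential: a somatic spiking waveform of duration T1
version: 1
dt: 0.05
calcium_exponents: [2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0]  # [Ca] = 10^-x mM, KCa only
protocols:
  activation:
    Kv:  {V0: -80, V1: -80, V2: 70, dV: 10, T1: 100, T2: 500, T3: 100, TA: 100, TB: 700}
    Nav: {V0: -80, V1: -80, V2: 70, dV: 10, T1: 20, T2: 50, T3: 30, TA: 18, TB: 100}
    Cav: {V0: -80, V1: -80, V2: 70, dV: 10, T1: 100, T2: 500, T3: 100, TA: 98, TB: 700}
    KCa: {V0: -80, V1: -80, V2: 70, dV: 10, T1: 100, T2: 500, T3: 100, TA: 95, TB: 605}
    Ih:  {V0: -40, V1: -150, V2: 0, dV: 10, T1: 100, T2: 2000, T3: 100, TA: 95, TB: 2105}
  inactivation:
    Kv:  {V0: -80, V1: -40, V2: 70, V3: 30, dV: 10, T1: 100, T2: 1500, T3: 50, T4: 100, TA: 1600, TB: 1700}
    Nav: {V0: -80, V1: -40, V2: 70, V3: 30, dV: 10, T1: 100, T2: 1500, T3: 50, T4: 100, TA: 1580, TB: 1750}
    Cav: {V0: -80, V1: -40, V2: 70, V3: 30, dV: 10, T1: 100, T2: 1500, T3: 50, T4: 100, TA: 1580, TB: 1750}
    KCa: {V0: -80, V1: -40, V2: 70, V3: 30, dV: 10, T1: 100, T2: 1500, T3: 50, T4: 100, TA: 1595, TB: 1700}
    Ih:  {V0: -40, V1: -150, V2: -40, V3: -120, dV: 10, T1: 100, T2: 1000, T3: 300, T4: 100, TA: 1095, TB: 1405}
  deactivation:
    Kv:  {V0: -80, V1: 70, V2: -100, V3: 40, dV: 10, T1: 100, T2: 300, T3: 200, T4: 100, TA: 400, TB: 600}
    Nav: {V0: -80, V1: 70, V2: -100, V3: 40, dV: 10, T1: 20, T2: 10, T3: 30, T4: 20, TA: 29, TB: 80}
    Cav: {V0: -80, V1: 70, V2: -100, V3: 40, dV: 10, T1: 100, T2: 300, T3: 200, T4: 100, TA: 380, TB: 700}
    KCa: {V0: -80, V1: 70, V2: -100, V3: 40, dV: 10, T1: 100, T2: 300, T3: 200, T4: 100, TA: 395, TB: 605}
    Ih:  {V0: -40, V1: -140, V2: -110, V3: 0, dV: 10, T1: 100, T2: 1500, T3: 500, T4: 400, TA: 1595, TB: 2105}
  ramp:
    Kv:  {V0: -80, V1: 70, T: [100, 800, 400, 400, 400, 200, 400, 100, 100], TA: 100, TB: 2800}
    Nav: {V0: -80, V1: 70, T: [100, 800, 400, 400, 400, 200, 400, 100, 100], TA: 98, TB: 2800}
    Cav: {V0: -80, V1: 70, T: [100, 800, 400, 400, 400, 200, 400, 100, 100], TA: 98, TB: 2800}
    KCa: {V0: -80, V1: 70, T: [100, 800, 400, 400, 400, 200, 400, 100, 100], TA: 100, TB: 2800}
    Ih:  {V0: -80, V1: 70, T: [100, 800, 400, 400, 400, 200, 400, 100, 100], TA: 100, TB: 2800}
  action_potential:
    Kv:  {T1: 1800, TA: 100, TB: 1800}
    Nav: {T1: 1800, TA: 98, TB: 1800}
    Cav: {T1: 1800, TA: 98, TB: 1800}
    KCa: {T1: 1800, TA: 95, TB: 1655}
    Ih:  {T1: 1800, TA: 95, TB: 1655}
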