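# Branched network with two inputs (x1, x2), two outputs (x9, x10) and
# allosteric cross-inhibition between the product branches (x8 inhibits r4,
# x7 inhibits r5).  The condensation step r3 carries an adjustable Michaelis
# constant K3 so the same model serves both the four-external scenario and
# the sensed-parameter scenario.  Topology follows the published branched
# example; all kinetic parameter values are fixture-chosen (see provenance).
name: branched
mu: 1.0
adjustable_parameters: {K3: 2.0}
species:
  - {name: x1, role: external}
  - {name: x2, role: external}
  - {name: x3, role: internal}
  - {name: x4, role: internal}
  - {name: x5, role: internal}
  - {name: x6, role: internal}
  - {name: x7, role: internal}
  - {name: x8, role: internal}
  - {name: x9, role: external}
  - {name: x10, role: external}
reactions:
  - id: r1
    expression: "(0.9*x1 - 0.3*x3) / ((0.2*x1 + 1)*(0.25*x3 + 1))"
    parameters: {}
  - id: r2
    expression: "(0.8*x2 - 0.25*x4) / ((0.15*x2 + 1)*(0.3*x4 + 1))"
    parameters: {}
  - id: r3
    expression: "(0.7*x3*x4 - 0.2*x5*x6) / ((x3/K3 + 1)*(0.3*x4 + 1)*(0.2*x5 + 0.25*x6 + 1))"
    parameters: {}
  - id: r4
    expression: "(0.85*x5 - 0.3*x7) / ((0.25*x5 + 1)*(0.2*x7 + 1)*(1 + 0.3*x8))"
    parameters: {}
  - id: r5
    expression: "(0.75*x6 - 0.25*x8) / ((0.2*x6 + 1)*(0.25*x8 + 1)*(1 + 0.25*x7))"
    parameters: {}
  - id: r6
    expression: "(0.8*x7 - 0.3*x9) / ((0.2*x7 + 1)*(0.2*x9 + 1))"
    parameters: {}
  - id: r7
    expression: "(0.7*x8 - 0.25*x10) / ((0.25*x8 + 1)*(0.2*x10 + 1))"
    parameters: {}
stoichiometry:
  r1: {x3: 1}
  r2: {x4: 1}
  r3: {x3: -1, x4: -1, x5: 1, x6: 1}
  r4: {x5: -1, x7: 1}
  r5: {x6: -1, x8: 1}
  r6: {x7: -1}
  r7: {x8: -1}
fixture:
  mode: [1, 1, 1, 1, 1, 1, 1]
  output_reaction: r6
  sensors: [x3, x4, x7, x8]
  unknowns: [x1, x2, x9, x10]
  known_externals: {}
  schedule:
    segments:
      - {t: 0,   values: {x1: 4.0, x2: 3.5, x9: 0.4, x10: 0.3}}
      - {t: 60,  values: {x1: 2.0}}
      - {t: 120, values: {x2: 5.5}}
      - {t: 180, values: {x9: 0.8}}
      - {t: 240, values: {x10: 0.6}}
    t_end: 300
  # initial state: the pathway adapted to a previous environment
  # (x1=2, x2=5, x9=0.6, x10=0.5), so the run starts with attainable
  # sensor values and genuine adaptation dynamics
  init:
    x_I: {x3: 2.184, x4: 4.868, x5: 3.068, x6: 2.998, x7: 1.603, x8: 1.563}
    e: {r1: 0.16, r2: 0.131, r3: 0.184, r4: 0.136, r5: 0.142, r6: 0.113, r7: 0.134}
provenance:
  printed: [topology with two inputs and two outputs, cross-inhibition,
            four sensors for four varying externals]
  fixture_chosen: [all kinetic parameter values, scheduled values,
                   initial conditions, K3 default]
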