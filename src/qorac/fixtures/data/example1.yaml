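# Four-step C/N assimilation pathway: uptake of external C (x1) to C' (x2),
# uptake of N to N' (x3), condensation to C3N2 (x4), and export.
# Rate-law expressions and stoichiometry are transcribed verbatim from the
# published model; entries listed under provenance.fixture_chosen were not
# printed and are this package's documented choices (notably Ntot = 10).
name: example1
mu: 1.0
species:
  - {name: x1, role: external}
  - {name: x2, role: internal}
  - {name: x3, role: internal}
  - {name: x4, role: internal}
reactions:
  - id: r1
    expression: "(0.6*x1 - 0.75*x2) / ((0.2*x1 + 1.0)*(0.33*x2 + 1.0))"
    parameters: {}
  - id: r2
    expression: "(Ntot - 3.0*x3) / ((0.5*x3 + 1)*(Ntot + 1))"
    parameters: {Ntot: 10.0}
  - id: r3
    expression: "(0.2*x2*x3 - 0.17*x4) / ((0.2*x3/5 + 1.0)*(0.33*x2 + 0.17*x4 + 1.0))"
    parameters: {}
  - id: r4
    expression: "(x4 - 0.0025) / (0.33*x4 + 1.0025)"
    parameters: {}
stoichiometry:
  r1: {x2: 1}
  r2: {x3: 1}
  r3: {x2: -1, x3: -1, x4: 1}
  r4: {x4: -1}
fixture:
  mode: [1, 1, 1, 1]
  output_reaction: r4
  sensors: [x2]
  unknowns: [x1]
  known_externals: {}
  schedule:
    segments:
      - {t: 0,   values: {x1: 3.0}}
      - {t: 50,  values: {x1: 1.2}}
      - {t: 100, values: {x1: 6.0}}
    t_end: 150
  init:
    x_I: {x2: 0.5, x3: 0.5, x4: 0.5}
    e: {r1: 0.25, r2: 0.25, r3: 0.25, r4: 0.25}
provenance:
  printed: [rate-law expressions, stoichiometry, mu, sensor choice x2,
            unknown external x1, schedule change times 50 and 100]
  fixture_chosen: [Ntot, scheduled x1 values, initial conditions]
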