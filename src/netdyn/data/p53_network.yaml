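# Reference 16-node p53 regulatory network (weighted-sum Boolean logic).
#
# This is a documented reconstruction of the simplified p53 DNA-damage-response
# model: DNA damage activates ATM/CHK2 signaling to p53; p53 drives the
# negative feedbacks through MDM2 and Wip1 (the source of pulsatile p53
# dynamics), the arrest arm through p21, the death arm through PTEN/BAX/
# caspase antagonized by AKT/BCL2, and the proliferation arm through the
# Rb/E2F1/Cyclin E axis with p14ARF feeding back on MDM2.
#
# Weights and basal levels are minimal signed integers chosen so that every
# node's local truth table is tie-free (audit with `netdyn audit`).
# Phenotype markers: proliferation = CyclinE, arrest = p21, death = caspase.
version: 1
nodes:
  - DNAdamage
  - ATM
  - CHK2
  - p53
  - MDM2
  - Wip1
  - p14ARF
  - AKT
  - PTEN
  - p21
  - CyclinE
  - Rb
  - E2F1
  - BCL2
  - BAX
  - caspase
links:
  - [DNAdamage, ATM, 2]
  - [Wip1, ATM, -3]
  - [ATM, CHK2, 2]
  - [CHK2, p53, 2]
  - [MDM2, p53, -3]
  - [p53, MDM2, 2]
  - [AKT, MDM2, 2]
  - [p14ARF, MDM2, -5]
  - [ATM, MDM2, -4]
  - [p53, Wip1, 2]
  - [E2F1, p14ARF, 2]
  - [PTEN, AKT, -2]
  - [p53, PTEN, 2]
  - [p53, p21, 2]
  - [AKT, p21, -3]
  - [E2F1, CyclinE, 1]
  - [p21, CyclinE, -4]
  - [CyclinE, Rb, -2]
  - [Rb, E2F1, -2]
  - [AKT, BCL2, 4]
  - [p53, BCL2, -2]
  - [p53, BAX, 2]
  - [BCL2, BAX, -3]
  - [BAX, caspase, 2]
basal:
  DNAdamage: -1
  ATM: -1
  CHK2: -1
  p53: -1
  MDM2: -1
  Wip1: -1
  p14ARF: -1
  AKT: 1
  PTEN: -1
  p21: -1
  CyclinE: 1
  Rb: 1
  E2F1: 1
  BCL2: 1
  BAX: -1
  caspase: -1
input_node: DNAdamage
marker_roles:
  proliferation: CyclinE
  arrest: p21
  death: caspase
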