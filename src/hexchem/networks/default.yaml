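# Default 15-species reaction network.
#
# A cyclic, count-conserving network in which every path decays back to the
# feedstock molecule 1.  Molecules 2/3 are a slow/fast-diffusing
# activator/inhibitor pair (written in the a + b => a + c catalytic form, with
# the catalyst on both sides so the event count scales with its abundance);
# molecules 4/5 are their spent forms; 8-11 is the bookkeeping cascade whose
# end product 11 enables informant-polymer replication; 13-15 is the cascade
# whose head 13 triggers boundary-box formation.  Productive steps consume one
# energy molecule 25 per event and their listed order is the energy priority
# under scarcity: activator maintenance first, then the bookkeeping cascades.
# Pure decay steps are free.
#
# Probabilities are tuning parameters: this set is calibrated so that, under
# the standard species table, cell-like boundary regions emerge and persist
# when energy is plentiful and collapse to extinction when it is absent.
conservation: true
rules:
  # activator autocatalysis: 1 + 2 -> 2 + 2
  - {reactants: {1: 1, 2: 1}, products: {2: 2}, p: 0.15, energy_cost: 1}
  # inhibitor production by the activator: 1 + 2 -> 3 + 2
  - {reactants: {1: 1, 2: 1}, products: {3: 1, 2: 1}, p: 0.02, energy_cost: 1}
  # replication bookkeeping cascade: 1 -> 8 -> 9 -> 10 -> 11 (activator-driven)
  - {reactants: {1: 1, 2: 1}, products: {8: 1, 2: 1}, p: 0.02, energy_cost: 1}
  - {reactants: {8: 1}, products: {9: 1}, p: 0.5, energy_cost: 1}
  - {reactants: {9: 1}, products: {10: 1}, p: 0.5, energy_cost: 1}
  - {reactants: {10: 1}, products: {11: 1}, p: 0.5, energy_cost: 1}
  # boundary bookkeeping cascade head: 13 triggers box formation
  - {reactants: {1: 1, 2: 1}, products: {13: 1, 2: 1}, p: 0.02, energy_cost: 1}
  # inhibition: 2 + 3 -> 4 + 3, plus spontaneous activator decay 2 -> 4
  - {reactants: {2: 1, 3: 1}, products: {4: 1, 3: 1}, p: 0.15}
  - {reactants: {2: 1}, products: {4: 1}, p: 0.03}
  # inhibitor decay: 3 -> 5
  - {reactants: {3: 1}, products: {5: 1}, p: 0.1}
  # returns to feedstock
  - {reactants: {4: 1}, products: {1: 1}, p: 0.5}
  - {reactants: {5: 1}, products: {1: 1}, p: 0.5}
  - {reactants: {11: 1}, products: {1: 1}, p: 0.1}
  - {reactants: {13: 1}, products: {14: 1}, p: 0.3}
  - {reactants: {14: 1}, products: {15: 1}, p: 0.5}
  - {reactants: {15: 1}, products: {1: 1}, p: 0.5}

polymer_triggers:
  formation_catalyst: 13
  formation_p: 0.2
  box_decay_p: 0.01
  polymer1_decay_p: 0.01
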