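# Default topologies for the nine invasion scenarios.
#
# Demes: pop1-pop3 are the sampled groups; ghost4-ghost6 are unsampled
# sources ("ghost populations"); anc is the native-range ancestor.
# ghost4 doubles as "the introduced population" (size N4) in the
# single-introduction scenarios.  Events are backward in time: a split
# moves all lineages of `from` into `to`; an admixture moves each lineage
# of `from` into donors[0] with probability r, else donors[1].  Time
# symbols resolve against ScenarioParameters (ti > td > td1; ta deeper).
#
# Scenarios 1-5 assume a single introduction (everything funnels through
# ghost4 at ti); 6-9 assume repeated introductions from distinct sources.
# The branching orders within each family are explicit,
# revisable defaults: edit this file, not the code, to try alternatives.
scenarios:
  1:  # simultaneous three-way divergence from the introduced population
    events:
      - {time: ti, kind: split, from: pop1, to: ghost4}
      - {time: ti, kind: split, from: pop2, to: ghost4}
      - {time: ti, kind: split, from: pop3, to: ghost4}
      - {time: ta, kind: split, from: ghost4, to: anc}
  2:  # stepwise divergence, topology (pop3, (pop1, pop2))
    events:
      - {time: td, kind: split, from: pop2, to: pop1}
      - {time: ti, kind: split, from: pop1, to: ghost4}
      - {time: ti, kind: split, from: pop3, to: ghost4}
      - {time: ta, kind: split, from: ghost4, to: anc}
  3:  # stepwise divergence, topology (pop2, (pop1, pop3))
    events:
      - {time: td, kind: split, from: pop3, to: pop1}
      - {time: ti, kind: split, from: pop1, to: ghost4}
      - {time: ti, kind: split, from: pop2, to: ghost4}
      - {time: ta, kind: split, from: ghost4, to: anc}
  4:  # as 2, but pop3 is a recent admixture of pop1 and pop2
    events:
      - {time: td1, kind: admixture, from: pop3, donors: [pop1, pop2]}
      - {time: td, kind: split, from: pop2, to: pop1}
      - {time: ti, kind: split, from: pop1, to: ghost4}
      - {time: ta, kind: split, from: ghost4, to: anc}
  5:  # as 3, but pop2 is a recent admixture of pop1 and pop3
    events:
      - {time: td1, kind: admixture, from: pop2, donors: [pop1, pop3]}
      - {time: td, kind: split, from: pop3, to: pop1}
      - {time: ti, kind: split, from: pop1, to: ghost4}
      - {time: ta, kind: split, from: ghost4, to: anc}
  6:  # three independent introductions from three divergent sources
    events:
      - {time: td1, kind: split, from: pop3, to: ghost6}
      - {time: td, kind: split, from: pop2, to: ghost5}
      - {time: ti, kind: split, from: pop1, to: ghost4}
      - {time: ta, kind: split, from: ghost4, to: anc}
      - {time: ta, kind: split, from: ghost5, to: anc}
      - {time: ta, kind: split, from: ghost6, to: anc}
  7:  # two sources; pop2 diverges from pop1 after its introduction
    events:
      - {time: td1, kind: split, from: pop2, to: pop1}
      - {time: td, kind: split, from: pop3, to: ghost5}
      - {time: ti, kind: split, from: pop1, to: ghost4}
      - {time: ta, kind: split, from: ghost4, to: anc}
      - {time: ta, kind: split, from: ghost5, to: anc}
  8:  # two sources; pop2 admixed between the two introduced lineages
    events:
      - {time: td1, kind: admixture, from: pop2, donors: [pop1, pop3]}
      - {time: td, kind: split, from: pop3, to: ghost5}
      - {time: ti, kind: split, from: pop1, to: ghost4}
      - {time: ta, kind: split, from: ghost4, to: anc}
      - {time: ta, kind: split, from: ghost5, to: anc}
  9:  # single introduction drawn from an admixed pool of two ghost sources
    events:
      - {time: td, kind: split, from: pop2, to: pop1}
      - {time: td, kind: split, from: pop3, to: pop1}
      - {time: ti, kind: admixture, from: pop1, donors: [ghost5, ghost6]}
      - {time: ta, kind: split, from: ghost5, to: anc}
      - {time: ta, kind: split, from: ghost6, to: anc}
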