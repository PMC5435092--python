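# Default atopic case definitions: ICPC-1 episode codes and the ATC
# prescription prefixes accepted as disorder-relevant medication evidence.
eczema:
  icpc_code: S87
  relevant_atc_prefixes: [D07]
asthma:
  icpc_code: R96
  relevant_atc_prefixes: [R03]
rhinitis:
  icpc_code: R97
  relevant_atc_prefixes: [R01AC, R01AD, R06]
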