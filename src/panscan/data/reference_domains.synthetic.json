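{
 "domains": [
  {
   "name": "GGDEF",
   "source_protein": "synthetic exemplar (DGC)",
   "asite_span": [
    103,
    108
   ],
   "isite_span": [
    95,
    99
   ],
   "catalytic_positions": [
    30,
    60,
    103,
    104,
    105,
    106,
    107,
    140
   ],
   "dyad_positions": null,
   "key_glutamate": null,
   "cog": "COG2199"
  },
  {
   "name": "EAL",
   "source_protein": "synthetic exemplar (PDE)",
   "asite_span": [
    8,
    11
   ],
   "isite_span": null,
   "catalytic_positions": [
    8,
    10,
    70,
    95,
    120,
    150
   ],
   "dyad_positions": null,
   "key_glutamate": 70,
   "cog": "COG2200"
  },
  {
   "name": "HD-GYP",
   "source_protein": "synthetic exemplar (PDE)",
   "asite_span": [
    120,
    123
   ],
   "isite_span": null,
   "catalytic_positions": [
    40,
    75,
    120,
    121,
    122
   ],
   "dyad_positions": [
    40,
    75
   ],
   "key_glutamate": null,
   "cog": "COG3437"
  }
 ]
}
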