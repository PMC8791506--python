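{
 "n_reactions": 2,
 "blocks": [
  [
   "S1"
  ],
  [
   "S2"
  ],
  [
   "E1"
  ],
  [
   "E2",
   "P1"
  ],
  [
   "P2"
  ]
 ]
}
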