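{
 "n_reactions": 1,
 "blocks": [
  [
   "S1",
   "E1",
   "P1"
  ]
 ]
}
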