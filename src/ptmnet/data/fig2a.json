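{
 "n_reactions": 4,
 "blocks": [
  [
   "S1",
   "P2"
  ],
  [
   "S2",
   "E1",
   "E4",
   "P1"
  ],
  [
   "S3",
   "P4"
  ],
  [
   "S4",
   "E2",
   "E3",
   "P3"
  ]
 ]
}
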