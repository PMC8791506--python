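{
 "n_reactions": 10,
 "blocks": [
  [
   "S1",
   "P2"
  ],
  [
   "S2",
   "E3",
   "E4",
   "P1"
  ],
  [
   "S3",
   "P6"
  ],
  [
   "S4",
   "S6",
   "P3",
   "P5"
  ],
  [
   "S5",
   "E7",
   "E8",
   "P4"
  ],
  [
   "S7",
   "P10"
  ],
  [
   "S8",
   "S10",
   "P7",
   "P9"
  ],
  [
   "S9",
   "P8"
  ],
  [
   "E1"
  ],
  [
   "E2"
  ],
  [
   "E5"
  ],
  [
   "E6"
  ],
  [
   "E9"
  ],
  [
   "E10"
  ]
 ]
}
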