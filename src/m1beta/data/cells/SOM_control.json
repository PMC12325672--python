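{
 "class": "SOM",
 "condition": "control",
 "compartments": [
  {
   "name": "soma",
   "L": 22,
   "diam": 16,
   "parent": -1,
   "zone": "soma"
  },
  {
   "name": "axon",
   "L": 100,
   "diam": 1.0,
   "parent": 0,
   "zone": "axon"
  },
  {
   "name": "dend",
   "L": 400,
   "diam": 2.5,
   "parent": 0,
   "zone": "dend"
  }
 ],
 "channels": {
  "na": [
   60,
   250,
   0
  ],
  "kdr": [
   6,
   50,
   0
  ],
  "bk": [
   3,
   0,
   0
  ],
  "leak": [
   0.08,
   0.08,
   0.08
  ]
 },
 "e_leak": [
  -70.0,
  -70.0,
  -70.0
 ],
 "cm": 1.0,
 "ra": 120.0,
 "vt": -60.0,
 "v_init": -70.0
}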