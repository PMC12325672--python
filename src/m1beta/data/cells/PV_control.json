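{
 "class": "PV",
 "condition": "control",
 "compartments": [
  {
   "name": "soma",
   "L": 20,
   "diam": 18,
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
   "L": 350,
   "diam": 2.5,
   "parent": 0,
   "zone": "dend"
  }
 ],
 "channels": {
  "na": [
   80,
   300,
   0
  ],
  "kdr": [
   15,
   80,
   0
  ],
  "bk": [
   1,
   0,
   0
  ],
  "leak": [
   0.15,
   0.15,
   0.15
  ]
 },
 "e_leak": [
  -70.0,
  -70.0,
  -70.0
 ],
 "cm": 1.0,
 "ra": 120.0,
 "vt": -57.0,
 "v_init": -70.0
}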