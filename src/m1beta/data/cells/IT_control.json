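{
 "class": "IT",
 "condition": "control",
 "compartments": [
  {
   "name": "soma",
   "L": 30,
   "diam": 22,
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
   "name": "basal",
   "L": 250,
   "diam": 3.0,
   "parent": 0,
   "zone": "basal"
  },
  {
   "name": "apic1",
   "L": 300,
   "diam": 3.5,
   "parent": 0,
   "zone": "apical"
  },
  {
   "name": "apic2",
   "L": 300,
   "diam": 2.5,
   "parent": 3,
   "zone": "apical"
  }
 ],
 "channels": {
  "na": [
   60,
   300,
   0,
   0,
   0
  ],
  "kdr": [
   8,
   60,
   0,
   0,
   0
  ],
  "bk": [
   3,
   0,
   0,
   0,
   0
  ],
  "leak": [
   0.06,
   0.06,
   0.06,
   0.06,
   0.06
  ]
 },
 "e_leak": [
  -72.0,
  -72.0,
  -72.0,
  -72.0,
  -72.0
 ],
 "cm": 1.0,
 "ra": 120.0,
 "vt": -58.0,
 "v_init": -70.0
}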