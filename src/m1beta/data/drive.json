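{
 "n_generators": 1000,
 "p_connect": 0.25,
 "class_weight_factor": {
  "IT": 1.0,
  "PT5B": 1.0,
  "CT": 1.0,
  "PV": 0.25,
  "SOM": 0.1
 },
 "pop_weight_factor": {
  "IT2/3": 0.7,
  "IT5A": 1.0,
  "IT4": 2.2,
  "IT5B": 2.2,
  "PT5B": 1.8
 },
 "unitary_epsp_mv": 0.5,
 "activated_motor_thalamus_range_hz": [
  0,
  10.0
 ],
 "activated_ih_multiplier": 0.25,
 "regions": {
  "VM": {
   "rate_range_hz": [
    0,
    5.0
   ],
   "motor_thalamus": true,
   "targets": [
    "IT2/3",
    "IT4",
    "IT5A",
    "PV2/3",
    "SOM2/3",
    "PV5A",
    "SOM5A"
   ]
  },
  "VL": {
   "rate_range_hz": [
    0,
    2.5
   ],
   "motor_thalamus": true,
   "targets": [
    "IT4",
    "IT5B",
    "PT5B",
    "PV5A",
    "PV5B",
    "SOM5B"
   ]
  },
  "S1": {
   "rate_range_hz": [
    0,
    5.0
   ],
   "motor_thalamus": false,
   "targets": [
    "IT2/3",
    "IT5A",
    "PV2/3",
    "SOM2/3",
    "PV5A",
    "SOM5A"
   ]
  },
  "S2": {
   "rate_range_hz": [
    0,
    5.0
   ],
   "motor_thalamus": false,
   "targets": [
    "IT2/3",
    "IT5A",
    "PV2/3"
   ]
  },
  "cM1": {
   "rate_range_hz": [
    0,
    2.5
   ],
   "motor_thalamus": false,
   "targets": [
    "IT5B",
    "PT5B",
    "IT6",
    "CT6",
    "PV5B",
    "PV6"
   ]
  },
  "M2": {
   "rate_range_hz": [
    0,
    2.5
   ],
   "motor_thalamus": false,
   "targets": [
    "IT5B",
    "PT5B",
    "IT6",
    "CT6",
    "PV5B",
    "PV6"
   ]
  },
  "OC": {
   "rate_range_hz": [
    0,
    5.0
   ],
   "motor_thalamus": false,
   "targets": [
    "IT6",
    "CT6",
    "PV6",
    "SOM6"
   ]
  }
 }
}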