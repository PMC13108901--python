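{
 "config": {
  "n_subjects": 5,
  "agent_mix": {
   "constructive": 1.0
  },
  "constructive_gamma": "inf",
  "dispersion": 1.5,
  "master_seed": 123
 },
 "subjects": [
  {
   "subject_id": "s000",
   "true_order": [
    "A",
    "H",
    "E",
    "G",
    "F",
    "B",
    "C",
    "D"
   ],
   "subjective_order": [
    "A",
    "E",
    "H",
    "F",
    "C",
    "G",
    "B",
    "D"
   ],
   "category": "consistent_incorrect",
   "coefficient": 1.0
  },
  {
   "subject_id": "s001",
   "true_order": [
    "B",
    "E",
    "H",
    "F",
    "A",
    "C",
    "D",
    "G"
   ],
   "subjective_order": [
    "B",
    "E",
    "A",
    "H",
    "F",
    "C",
    "D",
    "G"
   ],
   "category": "consistent_incorrect",
   "coefficient": 1.0
  },
  {
   "subject_id": "s002",
   "true_order": [
    "F",
    "A",
    "B",
    "G",
    "E",
    "H",
    "D",
    "C"
   ],
   "subjective_order": [
    "F",
    "G",
    "B",
    "E",
    "A",
    "H",
    "D",
    "C"
   ],
   "category": "consistent_incorrect",
   "coefficient": 1.0
  },
  {
   "subject_id": "s003",
   "true_order": [
    "F",
    "H",
    "A",
    "G",
    "B",
    "D",
    "C",
    "E"
   ],
   "subjective_order": [
    "H",
    "A",
    "G",
    "F",
    "B",
    "E",
    "C",
    "D"
   ],
   "category": "consistent_incorrect",
   "coefficient": 1.0
  },
  {
   "subject_id": "s004",
   "true_order": [
    "B",
    "C",
    "H",
    "E",
    "G",
    "A",
    "F",
    "D"
   ],
   "subjective_order": [
    "B",
    "C",
    "H",
    "E",
    "G",
    "A",
    "D",
    "F"
   ],
   "category": "consistent_incorrect",
   "coefficient": 1.0
  }
 ]
}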