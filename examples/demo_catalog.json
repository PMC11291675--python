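{
 "alleles": [
  {
   "locus": "A",
   "two_field": "A*01:01",
   "sequence": {
    "9": "F",
    "95": "V",
    "152": "A",
    "245": "A"
   },
   "exon_of_position": {
    "9": 2,
    "95": 3,
    "152": 3,
    "245": 4
   }
  },
  {
   "locus": "A",
   "two_field": "A*02:01",
   "sequence": {
    "9": "Y",
    "95": "L",
    "152": "V",
    "245": "A"
   },
   "exon_of_position": {
    "9": 2,
    "95": 3,
    "152": 3,
    "245": 4
   }
  },
  {
   "locus": "A",
   "two_field": "A*03:01",
   "sequence": {
    "9": "F",
    "95": "L",
    "152": "E",
    "245": "S"
   },
   "exon_of_position": {
    "9": 2,
    "95": 3,
    "152": 3,
    "245": 4
   }
  },
  {
   "locus": "A",
   "two_field": "A*24:02",
   "sequence": {
    "9": "S",
    "95": "I",
    "152": "A",
    "245": "S"
   },
   "exon_of_position": {
    "9": 2,
    "95": 3,
    "152": 3,
    "245": 4
   }
  },
  {
   "locus": "B",
   "two_field": "B*07:02",
   "sequence": {
    "45": "E",
    "70": "Q",
    "97": "S",
    "116": "Y",
    "178": "T"
   },
   "exon_of_position": {
    "45": 2,
    "70": 2,
    "97": 3,
    "116": 3,
    "178": 4
   }
  },
  {
   "locus": "B",
   "two_field": "B*08:01",
   "sequence": {
    "45": "E",
    "70": "N",
    "97": "T",
    "116": "D",
    "178": "K"
   },
   "exon_of_position": {
    "45": 2,
    "70": 2,
    "97": 3,
    "116": 3,
    "178": 4
   }
  },
  {
   "locus": "B",
   "two_field": "B*27:05",
   "sequence": {
    "45": "K",
    "70": "K",
    "97": "N",
    "116": "D",
    "178": "T"
   },
   "exon_of_position": {
    "45": 2,
    "70": 2,
    "97": 3,
    "116": 3,
    "178": 4
   }
  },
  {
   "locus": "B",
   "two_field": "B*44:02",
   "sequence": {
    "45": "T",
    "70": "N",
    "97": "R",
    "116": "D",
    "178": "K"
   },
   "exon_of_position": {
    "45": 2,
    "70": 2,
    "97": 3,
    "116": 3,
    "178": 4
   }
  },
  {
   "locus": "C",
   "two_field": "C*06:02",
   "sequence": {
    "99": "S",
    "156": "L",
    "304": "G"
   },
   "exon_of_position": {
    "99": 3,
    "156": 3,
    "304": 4
   }
  },
  {
   "locus": "C",
   "two_field": "C*07:01",
   "sequence": {
    "99": "Y",
    "156": "R",
    "304": "G"
   },
   "exon_of_position": {
    "99": 3,
    "156": 3,
    "304": 4
   }
  },
  {
   "locus": "C",
   "two_field": "C*07:02",
   "sequence": {
    "99": "Y",
    "156": "L",
    "304": "E"
   },
   "exon_of_position": {
    "99": 3,
    "156": 3,
    "304": 4
   }
  },
  {
   "locus": "DRB1",
   "two_field": "DRB1*03:01",
   "sequence": {
    "11": "S",
    "13": "F",
    "86": "V",
    "233": "K"
   },
   "exon_of_position": {
    "11": 2,
    "13": 2,
    "86": 2,
    "233": 3
   }
  },
  {
   "locus": "DRB1",
   "two_field": "DRB1*15:01",
   "sequence": {
    "11": "S",
    "13": "H",
    "86": "G",
    "233": "K"
   },
   "exon_of_position": {
    "11": 2,
    "13": 2,
    "86": 2,
    "233": 3
   }
  },
  {
   "locus": "DRB1",
   "two_field": "DRB1*04:01",
   "sequence": {
    "11": "V",
    "13": "F",
    "86": "V",
    "233": "K"
   },
   "exon_of_position": {
    "11": 2,
    "13": 2,
    "86": 2,
    "233": 3
   }
  },
  {
   "locus": "DRB1",
   "two_field": "DRB1*04:04",
   "sequence": {
    "11": "V",
    "13": "R",
    "86": "G",
    "233": "R"
   },
   "exon_of_position": {
    "11": 2,
    "13": 2,
    "86": 2,
    "233": 3
   }
  },
  {
   "locus": "DRB1",
   "two_field": "DRB1*01:01",
   "sequence": {
    "11": "L",
    "13": "H",
    "86": "V",
    "233": "K"
   },
   "exon_of_position": {
    "11": 2,
    "13": 2,
    "86": 2,
    "233": 3
   }
  },
  {
   "locus": "DRB1",
   "two_field": "DRB1*07:01",
   "sequence": {
    "11": "L",
    "13": "R",
    "86": "G",
    "233": "R"
   },
   "exon_of_position": {
    "11": 2,
    "13": 2,
    "86": 2,
    "233": 3
   }
  },
  {
   "locus": "DQA1",
   "two_field": "DQA1*01:01",
   "sequence": {
    "34": "Q",
    "52": "R"
   },
   "exon_of_position": {
    "34": 2,
    "52": 2
   }
  },
  {
   "locus": "DQA1",
   "two_field": "DQA1*03:01",
   "sequence": {
    "34": "E",
    "52": "H"
   },
   "exon_of_position": {
    "34": 2,
    "52": 2
   }
  },
  {
   "locus": "DQA1",
   "two_field": "DQA1*05:01",
   "sequence": {
    "34": "Q",
    "52": "S"
   },
   "exon_of_position": {
    "34": 2,
    "52": 2
   }
  },
  {
   "locus": "DQB1",
   "two_field": "DQB1*02:01",
   "sequence": {
    "57": "A",
    "71": "K",
    "203": "I"
   },
   "exon_of_position": {
    "57": 2,
    "71": 2,
    "203": 3
   }
  },
  {
   "locus": "DQB1",
   "two_field": "DQB1*03:01",
   "sequence": {
    "57": "D",
    "71": "T",
    "203": "V"
   },
   "exon_of_position": {
    "57": 2,
    "71": 2,
    "203": 3
   }
  },
  {
   "locus": "DQB1",
   "two_field": "DQB1*03:02",
   "sequence": {
    "57": "A",
    "71": "R",
    "203": "V"
   },
   "exon_of_position": {
    "57": 2,
    "71": 2,
    "203": 3
   }
  },
  {
   "locus": "DQB1",
   "two_field": "DQB1*06:02",
   "sequence": {
    "57": "D",
    "71": "T",
    "203": "I"
   },
   "exon_of_position": {
    "57": 2,
    "71": 2,
    "203": 3
   }
  },
  {
   "locus": "DPB1",
   "two_field": "DPB1*04:01",
   "sequence": {
    "8": "V",
    "170": "I"
   },
   "exon_of_position": {
    "8": 2,
    "170": 3
   }
  },
  {
   "locus": "DPB1",
   "two_field": "DPB1*02:01",
   "sequence": {
    "8": "L",
    "170": "I"
   },
   "exon_of_position": {
    "8": 2,
    "170": 3
   }
  },
  {
   "locus": "DPB1",
   "two_field": "DPB1*04:02",
   "sequence": {
    "8": "V",
    "170": "T"
   },
   "exon_of_position": {
    "8": 2,
    "170": 3
   }
  },
  {
   "locus": "DPA1",
   "two_field": "DPA1*01:03",
   "sequence": {
    "31": "M",
    "83": "T"
   },
   "exon_of_position": {
    "31": 2,
    "83": 3
   }
  },
  {
   "locus": "DPA1",
   "two_field": "DPA1*02:01",
   "sequence": {
    "31": "Q",
    "83": "A"
   },
   "exon_of_position": {
    "31": 2,
    "83": 3
   }
  }
 ]
}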