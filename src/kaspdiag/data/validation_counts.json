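{
 "description": "Summary counts from the original 152-sample field validation of the cassava Bemisia tabaci KASP panel against NextRAD reference genotyping. Per-sample records expanded from these counts are synthetic (ids and non-mismatch countries are invented).",
 "n_samples": 152,
 "cohort": [
  {
   "reference": "SSA-ECA",
   "assigned": "SSA-ECA",
   "coi": "SSA1-SG1",
   "count": 24
  },
  {
   "reference": "SSA-ECA",
   "assigned": "SSA-ECA",
   "coi": "SSA1-SG2",
   "count": 6
  },
  {
   "reference": "SSA-ECA",
   "assigned": "SSA-ECA",
   "coi": "SSA1-SG1/SG2",
   "count": 1
  },
  {
   "reference": "SSA-ECA",
   "assigned": "SSA-WA",
   "coi": "SSA1-SG2",
   "count": 1,
   "country": "Kenya"
  },
  {
   "reference": "SSA-WA",
   "assigned": "SSA-WA",
   "coi": "SSA1-SG1",
   "count": 13
  },
  {
   "reference": "SSA-WA",
   "assigned": "SSA-WA",
   "coi": "SSA1-SG5",
   "count": 27
  },
  {
   "reference": "SSA-WA",
   "assigned": "SSA-WA",
   "coi": "SSA2",
   "count": 1
  },
  {
   "reference": "SSA-CA",
   "assigned": "SSA-CA",
   "coi": "SSA1-SG1",
   "count": 2
  },
  {
   "reference": "SSA-CA",
   "assigned": "SSA-CA",
   "coi": "unknown",
   "count": 2
  },
  {
   "reference": "SSA-ESA",
   "assigned": "SSA-ESA",
   "coi": "SSA1-SG3",
   "count": 41
  },
  {
   "reference": "SSA2",
   "assigned": "SSA2",
   "coi": "SSA2",
   "count": 22
  },
  {
   "reference": "SSA2",
   "assigned": "SSA2",
   "coi": "SSA3",
   "count": 3
  },
  {
   "reference": "SSA2",
   "assigned": "SSA2",
   "coi": "SSA4",
   "count": 1
  },
  {
   "reference": "SSA4",
   "assigned": "SSA4",
   "coi": "SSA4",
   "count": 8
  }
 ],
 "markers": {
  "BTS99-319": [
   {
    "reference_groups": [
     "SSA-ECA",
     "SSA-WA"
    ],
    "expected_state": "XX",
    "observed": {
     "XX": 73
    },
    "mismatch_countries": []
   },
   {
    "reference_groups": [
     "SSA-ESA",
     "SSA-CA",
     "SSA2",
     "SSA4"
    ],
    "expected_state": "YY",
    "observed": {
     "YY": 78,
     "XX": 1
    },
    "mismatch_countries": [
     "Malawi"
    ]
   }
  ],
  "BTS22-762": [
   {
    "reference_groups": [
     "SSA-ECA"
    ],
    "expected_state": "XX",
    "observed": {
     "XX": 31,
     "YY": 1
    },
    "mismatch_countries": [
     "Kenya"
    ]
   },
   {
    "reference_groups": [
     "SSA-WA"
    ],
    "expected_state": "YY",
    "observed": {
     "YY": 41
    },
    "mismatch_countries": []
   }
  ],
  "BTS141": [
   {
    "reference_groups": [
     "SSA2",
     "SSA4"
    ],
    "expected_state": "XX",
    "observed": {
     "XX": 34,
     "XY": 1
    },
    "mismatch_countries": [
     "DRC"
    ]
   },
   {
    "reference_groups": [
     "SSA-ECA",
     "SSA-WA",
     "SSA-ESA",
     "SSA-CA"
    ],
    "expected_state": "YY",
    "observed": {
     "YY": 117
    },
    "mismatch_countries": []
   }
  ],
  "BTS55-473": [
   {
    "reference_groups": [
     "SSA2"
    ],
    "expected_state": "XX",
    "observed": {
     "XX": 26
    },
    "mismatch_countries": []
   },
   {
    "reference_groups": [
     "SSA4"
    ],
    "expected_state": "YY",
    "observed": {
     "YY": 8
    },
    "mismatch_countries": []
   }
  ],
  "BTS613": [
   {
    "reference_groups": [
     "SSA-ESA",
     "SSA-CA"
    ],
    "expected_state": "XX",
    "observed": {
     "XX": 45
    },
    "mismatch_countries": []
   },
   {
    "reference_groups": [
     "SSA-ECA",
     "SSA-WA",
     "SSA2",
     "SSA4"
    ],
    "expected_state": "YY",
    "observed": {
     "YY": 107
    },
    "mismatch_countries": []
   }
  ],
  "BTS46-203": [
   {
    "reference_groups": [
     "SSA-ESA"
    ],
    "expected_state": "XX",
    "observed": {
     "XX": 39,
     "XY": 2
    },
    "mismatch_countries": [
     "Kenya",
     "Tanzania"
    ]
   },
   {
    "reference_groups": [
     "SSA-CA"
    ],
    "expected_state": "YY",
    "observed": {
     "YY": 2,
     "XY": 2
    },
    "mismatch_countries": [
     "DRC"
    ]
   }
  ],
  "BTS1161": [
   {
    "reference_groups": [
     "SSA-ESA"
    ],
    "expected_state": "XX",
    "observed": {
     "XX": 33,
     "XY": 8
    },
    "mismatch_countries": [
     "Malawi",
     "Mozambique"
    ]
   },
   {
    "reference_groups": [
     "SSA-CA"
    ],
    "expected_state": "YY",
    "observed": {
     "YY": 4
    },
    "mismatch_countries": []
   }
  ]
 }
}
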