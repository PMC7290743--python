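{
 "name": "cassava-bemisia-v1",
 "version": "1.0",
 "groups": [
  "SSA-ECA",
  "SSA-WA",
  "SSA-ESA",
  "SSA-CA",
  "SSA2",
  "SSA4"
 ],
 "markers": [
  {
   "id": "BTS99-319",
   "contig": "PGTP01000606.1",
   "position": 849342,
   "allele_x": "A",
   "allele_y": "G",
   "scope": [
    "SSA-ECA",
    "SSA-WA",
    "SSA-ESA",
    "SSA-CA",
    "SSA2",
    "SSA4"
   ],
   "partition": {
    "XX": [
     "SSA-ECA",
     "SSA-WA"
    ],
    "YY": [
     "SSA-ESA",
     "SSA-CA",
     "SSA2",
     "SSA4"
    ]
   },
   "fallback": null,
   "metadata": {
    "region": "intergenic",
    "amplicon": {
     "contig": "PGTP01000606.1",
     "range": [
      849024,
      849984
     ],
     "band_bp": 940
    },
    "kasp_primers": {
     "allele_x": "CTCAAATTTAAAATACGATTTCAATTACCATT",
     "allele_y": "CTCAAATTTAAAATACGATTTCAATTACCATC",
     "common": "GCTGCATATTATACCGCATGAAAGCTAAA",
     "size_bp": 40
    },
    "position_inferred": true,
    "gateway": true
   }
  },
  {
   "id": "BTS22-762",
   "contig": "PGTP01001647.1",
   "position": 63085,
   "allele_x": "A",
   "allele_y": "G",
   "scope": [
    "SSA-ECA",
    "SSA-WA"
   ],
   "partition": {
    "XX": [
     "SSA-ECA"
    ],
    "YY": [
     "SSA-WA"
    ]
   },
   "fallback": null,
   "metadata": {
    "region": "Ssa12858; exon",
    "amplicon": {
     "contig": "PGTP01001647.1",
     "range": [
      62324,
      63244
     ],
     "band_bp": 880
    },
    "kasp_primers": {
     "allele_x": "CAGTCAATTAAAAGACGTCTCGCTAA",
     "allele_y": "CAGTCAATTAAAAGACGTCTCGCTAG",
     "common": "GTCGCTGTCTTGTTTTCCCTCCAT",
     "size_bp": 50
    },
    "position_inferred": true
   }
  },
  {
   "id": "BTS141",
   "contig": "PGTP01000392.1",
   "position": 896310,
   "allele_x": "T",
   "allele_y": "C",
   "scope": [
    "SSA-ECA",
    "SSA-WA",
    "SSA-ESA",
    "SSA-CA",
    "SSA2",
    "SSA4"
   ],
   "partition": {
    "XX": [
     "SSA2",
     "SSA4"
    ],
    "YY": [
     "SSA-ECA",
     "SSA-WA",
     "SSA-ESA",
     "SSA-CA"
    ]
   },
   "fallback": null,
   "metadata": {
    "region": "intergenic",
    "amplicon": {
     "contig": "PGTP01000392.1",
     "range": [
      896170,
      897370
     ],
     "band_bp": 1150
    },
    "kasp_primers": {
     "allele_x": "TACTATTTCTAGCAAAGCGAATTTAAATCATA",
     "allele_y": "CTATTTCTAGCAAAGCGAATTTAAATCATG",
     "common": "GGAGTGCTATAAAGCGACCTATATGTAT",
     "size_bp": 36
    },
    "position_inferred": true
   }
  },
  {
   "id": "BTS55-473",
   "contig": "PGTP01143321.1",
   "position": 560123,
   "allele_x": "T",
   "allele_y": "C",
   "scope": [
    "SSA-ECA",
    "SSA-WA",
    "SSA-ESA",
    "SSA-CA",
    "SSA2",
    "SSA4"
   ],
   "partition": {
    "XX": [
     "SSA2"
    ],
    "YY": [
     "SSA-ECA",
     "SSA-WA",
     "SSA-ESA",
     "SSA-CA",
     "SSA4"
    ]
   },
   "fallback": null,
   "metadata": {
    "region": "intergenic",
    "amplicon": {
     "contig": "PGTP01143321.1",
     "range": [
      559651,
      560491
     ],
     "band_bp": 815
    },
    "kasp_primers": {
     "allele_x": "CCGCACAGGAGACCCAAGTC",
     "allele_y": "ACCGCACAGGAGACCCAAGTT",
     "common": "TAATAAGCCCGACATGCCGCTCTTT",
     "size_bp": 38
    },
    "position_inferred": true
   }
  },
  {
   "id": "BTS613",
   "contig": "PGTP01000317.1",
   "position": 29372,
   "allele_x": "G",
   "allele_y": "A",
   "scope": [
    "SSA-ECA",
    "SSA-WA",
    "SSA-ESA",
    "SSA-CA",
    "SSA2",
    "SSA4"
   ],
   "partition": {
    "XX": [
     "SSA-ESA",
     "SSA-CA"
    ],
    "YY": [
     "SSA-ECA",
     "SSA-WA",
     "SSA2",
     "SSA4"
    ]
   },
   "fallback": null,
   "metadata": {
    "region": "intergenic",
    "amplicon": {
     "contig": "PGTP01000317.1",
     "range": [
      28760,
      29515
     ],
     "band_bp": 730
    },
    "kasp_primers": {
     "allele_x": "GGTAGAGCGGCGCTTGGTC",
     "allele_y": "ATGGTAGAGCGGCGCTTGGTT",
     "common": "ACTTCGGCTTTGAACTTCCCGCAAA",
     "size_bp": 30
    },
    "position_inferred": true
   }
  },
  {
   "id": "BTS46-203",
   "contig": "PGTP01000379.1",
   "position": 1505568,
   "allele_x": "A",
   "allele_y": "G",
   "scope": [
    "SSA-ESA",
    "SSA-CA"
   ],
   "partition": {
    "XX": [
     "SSA-ESA"
    ],
    "YY": [
     "SSA-CA"
    ]
   },
   "fallback": "BTS1161",
   "metadata": {
    "region": "intron of Ssa00724",
    "amplicon": {
     "contig": "PGTP01000379.1",
     "range": [
      1505366,
      1505786
     ],
     "band_bp": 390
    },
    "kasp_primers": {
     "allele_x": "GGTGCATCGTATCGCATCTCTGA",
     "allele_y": "GTGCATCGTATCGCATCTCTGG",
     "common": "CATATAACTACGCGCAACGCAACGTA",
     "size_bp": 62
    },
    "position_inferred": true
   }
  },
  {
   "id": "BTS1161",
   "contig": "PGTP01001427.1",
   "position": 372804,
   "allele_x": "C",
   "allele_y": "A",
   "scope": [
    "SSA-ESA",
    "SSA-CA"
   ],
   "partition": {
    "XX": [
     "SSA-ESA"
    ],
    "YY": [
     "SSA-CA"
    ]
   },
   "fallback": null,
   "metadata": {
    "region": "intron of Ssa00849",
    "amplicon": {
     "contig": "PGTP01001427.1",
     "range": [
      371644,
      372644
     ],
     "band_bp": 500
    },
    "kasp_primers": {
     "allele_x": "AAGTCTTGCTGCTATGGCTTAGTTC",
     "allele_y": "AAAGTCTTGCTGCTATGGCTTAGTTA",
     "common": "CCCCATGTAGAGCTCCAGGTAAAAT",
     "size_bp": 60
    },
    "position_inferred": true,
    "nextrad_alleles": {
     "SSA-ESA": "A",
     "SSA-CA": "G"
    },
    "position_note": "name offset exceeds printed amplicon range; coordinate unverified"
   }
  }
 ],
 "tree": {
  "marker": "BTS99-319",
  "confirmations": [],
  "edges": {
   "XX": {
    "marker": "BTS22-762",
    "confirmations": [],
    "edges": {
     "XX": {
      "leaf": "SSA-ECA"
     },
     "YY": {
      "leaf": "SSA-WA"
     }
    }
   },
   "YY": {
    "marker": "BTS141",
    "confirmations": [
     "BTS613"
    ],
    "edges": {
     "XX": {
      "marker": "BTS55-473",
      "confirmations": [],
      "edges": {
       "XX": {
        "leaf": "SSA2"
       },
       "YY": {
        "leaf": "SSA4"
       }
      }
     },
     "YY": {
      "marker": "BTS46-203",
      "confirmations": [
       "BTS1161"
      ],
      "edges": {
       "XX": {
        "leaf": "SSA-ESA"
       },
       "YY": {
        "leaf": "SSA-CA"
       }
      }
     }
    }
   }
  }
 },
 "metadata": {
  "organism": "Bemisia tabaci (cassava-colonising, sub-Saharan Africa)",
  "reference_assembly": "GenBank PGTP01000000 (B. tabaci SSA1 SSA-ECA)",
  "gateway_marker": "BTS99-319",
  "notes": [
   "Marker positions are inferred from amplicon range start plus the trailing number in the marker id; metadata only.",
   "BTS1161 nextrad_alleles record the reference-sequencing allele labels, which differ from the KASP allele space; no strand conversion is attempted.",
   "Tree topology among the non-{SSA-ECA,SSA-WA} markers is the package's reconstruction of the published decision flow."
  ]
 }
}
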