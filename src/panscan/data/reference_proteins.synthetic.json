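{
 "proteins": [
  {
   "name": "cdgA",
   "plasmid": false,
   "tm_count": 0,
   "expected_class": "DGC",
   "domains": [
    {
     "kind": "GGDEF",
     "span": [
      200,
      370
     ],
     "asite_span": [
      303,
      308
     ],
     "protected": [
      230,
      260,
      295,
      296,
      297,
      298,
      303,
      304,
      305,
      306,
      307,
      340
     ],
     "grade": "intact"
    },
    {
     "kind": "EAL",
     "span": [
      382,
      562
     ],
     "asite_span": [
      390,
      393
     ],
     "protected": [
      390,
      391,
      392,
      452,
      477,
      502,
      532
     ],
     "grade": "atypical"
    }
   ]
  },
  {
   "name": "cdgB",
   "plasmid": false,
   "tm_count": 0,
   "expected_class": "DGC",
   "domains": [
    {
     "kind": "GGDEF",
     "span": [
      250,
      420
     ],
     "asite_span": [
      353,
      358
     ],
     "protected": [
      280,
      310,
      345,
      346,
      347,
      348,
      353,
      354,
      355,
      356,
      357,
      390
     ],
     "grade": "intact"
    }
   ]
  },
  {
   "name": "cdgC",
   "plasmid": false,
   "tm_count": 10,
   "expected_class": "DGC",
   "domains": [
    {
     "kind": "GGDEF",
     "span": [
      495,
      665
     ],
     "asite_span": [
      598,
      603
     ],
     "protected": [
      525,
      555,
      590,
      591,
      592,
      593,
      598,
      599,
      600,
      601,
      602,
      635
     ],
     "grade": "intact"
    },
    {
     "kind": "EAL",
     "span": [
      675,
      855
     ],
     "asite_span": [
      683,
      686
     ],
     "protected": [
      683,
      684,
      685,
      745,
      770,
      795,
      825
     ],
     "grade": "degenerate"
    }
   ]
  },
  {
   "name": "cdgD",
   "plasmid": false,
   "tm_count": 0,
   "expected_class": "DGC",
   "domains": [
    {
     "kind": "GGDEF",
     "span": [
      60,
      230
     ],
     "asite_span": [
      163,
      168
     ],
     "protected": [
      90,
      120,
      155,
      156,
      157,
      158,
      163,
      164,
      165,
      166,
      167,
      200
     ],
     "grade": "intact"
    }
   ]
  },
  {
   "name": "cdgE",
   "plasmid": false,
   "tm_count": 0,
   "expected_class": "DGC",
   "domains": [
    {
     "kind": "GGDEF",
     "span": [
      150,
      320
     ],
     "asite_span": [
      253,
      258
     ],
     "protected": [
      180,
      210,
      245,
      246,
      247,
      248,
      253,
      254,
      255,
      256,
      257,
      290
     ],
     "grade": "intact"
    }
   ]
  },
  {
   "name": "cdgF",
   "plasmid": false,
   "tm_count": 10,
   "expected_class": "bifunctional_candidate",
   "domains": [
    {
     "kind": "GGDEF",
     "span": [
      495,
      665
     ],
     "asite_span": [
      598,
      603
     ],
     "protected": [
      525,
      555,
      590,
      591,
      592,
      593,
      598,
      599,
      600,
      601,
      602,
      635
     ],
     "grade": "intact"
    },
    {
     "kind": "EAL",
     "span": [
      675,
      855
     ],
     "asite_span": [
      683,
      686
     ],
     "protected": [
      683,
      684,
      685,
      745,
      770,
      795,
      825
     ],
     "grade": "intact"
    }
   ]
  },
  {
   "name": "rmdA",
   "plasmid": false,
   "tm_count": 0,
   "expected_class": "PDE",
   "domains": [
    {
     "kind": "GGDEF",
     "span": [
      200,
      370
     ],
     "asite_span": [
      303,
      308
     ],
     "protected": [
      230,
      260,
      295,
      296,
      297,
      298,
      303,
      304,
      305,
      306,
      307,
      340
     ],
     "grade": "atypical"
    },
    {
     "kind": "EAL",
     "span": [
      382,
      562
     ],
     "asite_span": [
      390,
      393
     ],
     "protected": [
      390,
      391,
      392,
      452,
      477,
      502,
      532
     ],
     "grade": "intact"
    }
   ]
  },
  {
   "name": "rmdB",
   "plasmid": false,
   "tm_count": 6,
   "expected_class": "PDE",
   "domains": [
    {
     "kind": "GGDEF",
     "span": [
      291,
      461
     ],
     "asite_span": [
      394,
      399
     ],
     "protected": [
      321,
      351,
      386,
      387,
      388,
      389,
      394,
      395,
      396,
      397,
      398,
      431
     ],
     "grade": "atypical"
    },
    {
     "kind": "EAL",
     "span": [
      473,
      653
     ],
     "asite_span": [
      481,
      484
     ],
     "protected": [
      481,
      482,
      483,
      543,
      568,
      593,
      623
     ],
     "grade": "intact"
    }
   ]
  },
  {
   "name": "hdgA",
   "plasmid": false,
   "tm_count": 6,
   "expected_class": "PDE",
   "domains": [
    {
     "kind": "HD-GYP",
     "span": [
      291,
      461
     ],
     "asite_span": [
      411,
      414
     ],
     "protected": [
      331,
      366,
      411,
      412,
      413
     ],
     "grade": "intact"
    }
   ]
  },
  {
   "name": "hdgB",
   "plasmid": false,
   "tm_count": 6,
   "expected_class": "degenerate",
   "domains": [
    {
     "kind": "HD-GYP",
     "span": [
      291,
      461
     ],
     "asite_span": [
      411,
      414
     ],
     "protected": [
      331,
      366,
      411,
      412,
      413
     ],
     "grade": "degenerate"
    }
   ]
  },
  {
   "name": "pcdgG",
   "plasmid": true,
   "tm_count": 0,
   "expected_class": "DGC",
   "domains": [
    {
     "kind": "GGDEF",
     "span": [
      60,
      230
     ],
     "asite_span": [
      163,
      168
     ],
     "protected": [
      90,
      120,
      155,
      156,
      157,
      158,
      163,
      164,
      165,
      166,
      167,
      200
     ],
     "grade": "intact"
    }
   ]
  },
  {
   "name": "bldD",
   "plasmid": false,
   "tm_count": 0,
   "expected_class": "none",
   "domains": []
  }
 ]
}
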