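{
 "R": 0.4,
 "resolution": 0.05,
 "probe": {
  "dt": 0.01,
  "n_steps": 30000,
  "outer_ics": [
   [
    1.5,
    0.0
   ],
   [
    -1.5,
    0.0
   ]
  ],
  "fp_perturbation": 0.01,
  "amp_tol": 0.001
 },
 "curve_metadata": [
  {
   "branch": [
    1,
    1
   ],
   "family": "SN",
   "side_labels": [
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "bistable",
     "rest"
    ],
    [
     "bursting",
     "rest"
    ],
    [
     "bursting",
     "rest"
    ]
   ]
  },
  {
   "branch": [
    1,
    -1
   ],
   "family": "SN",
   "side_labels": [
    [
     "bistable",
     "bursting"
    ],
    [
     "bistable",
     "bursting"
    ],
    [
     "bistable",
     "bursting"
    ],
    [
     "rest",
     "bursting"
    ],
    [
     "rest",
     "bursting"
    ],
    [
     "rest",
     "bursting"
    ],
    [
     "rest",
     "bursting"
    ]
   ]
  },
  {
   "branch": [
    -1,
    1
   ],
   "family": "SN",
   "side_labels": [
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ]
   ]
  },
  {
   "branch": [
    -1,
    -1
   ],
   "family": "SN",
   "side_labels": [
    [
     "bistable",
     "bursting"
    ],
    [
     "rest",
     "bursting"
    ],
    [
     "rest",
     "bistable"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ]
   ]
  },
  {
   "family": "Hopf",
   "side_labels": [
    [
     "bursting",
     "rest"
    ],
    [
     "bursting",
     "bistable"
    ],
    [
     "bursting",
     "rest"
    ],
    [
     "bursting",
     "rest"
    ],
    [
     "bursting",
     "rest"
    ],
    [
     "bursting",
     "rest"
    ],
    [
     "bursting",
     "rest"
    ]
   ]
  },
  {
   "family": "Hopf",
   "side_labels": [
    [
     "bursting",
     "rest"
    ],
    [
     "bursting",
     "rest"
    ],
    [
     "bursting",
     "rest"
    ],
    [
     "bursting",
     "rest"
    ],
    [
     "bursting",
     "rest"
    ],
    [
     "bursting",
     "rest"
    ],
    [
     "rest",
     "rest"
    ]
   ]
  },
  {
   "family": "Hopf",
   "side_labels": [
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ],
    [
     "rest",
     "rest"
    ]
   ]
  },
  {
   "family": "SN"
  },
  {
   "family": "global"
  },
  {
   "family": "global"
  },
  {
   "family": "global"
  }
 ],
 "note": "smallest round radius with all six curve types"
}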