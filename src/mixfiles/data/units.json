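{
  "uriPrefix": "http://purl.obolibrary.org/obo/",
  "units": [
    {"common": "%",        "uri": "UO_0000187", "minchiCode": "pp", "scale": 1},
    {"common": "w/v%",     "uri": "UO_0000164", "minchiCode": "wv", "scale": 0.01},
    {"common": "w/w%",     "uri": "UO_0000163", "minchiCode": "wf", "scale": 0.01},
    {"common": "v/v%",     "uri": "UO_0000205", "minchiCode": "vf", "scale": 0.01},
    {"common": "mol/mol%", "uri": "UO_0000076", "minchiCode": "mf", "scale": 0.01},
    {"common": "mol/L",    "uri": "UO_0000062", "minchiCode": "mr", "scale": 1},
    {"common": "mmol/L",   "uri": "UO_0000063", "minchiCode": "mr", "scale": 1e-3},
    {"common": "μmol/L", "uri": "UO_0000064", "minchiCode": "mr", "scale": 1e-6},
    {"common": "nmol/L",   "uri": "UO_0000065", "minchiCode": "mr", "scale": 1e-9},
    {"common": "pmol/L",   "uri": "UO_0000066", "minchiCode": "mr", "scale": 1e-12},
    {"common": "g/L",      "uri": "UO_0000175", "minchiCode": "wv", "scale": 1e-3},
    {"common": "mg/L",     "uri": "UO_0000273", "minchiCode": "wv", "scale": 1e-6},
    {"common": "μg/L",   "uri": "UO_0000275", "minchiCode": "wv", "scale": 1e-9},
    {"common": "mol/kg",   "uri": "UO_0000068", "minchiCode": "mb", "scale": 1},
    {"common": "ratio",    "uri": "UO_0000190", "minchiCode": "vp", "scale": 1}
  ]
}
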