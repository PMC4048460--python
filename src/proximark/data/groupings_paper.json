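{
  "all": [
    "CSF",
    "3rd-Ventricle",
    "4th-Ventricle",
    "Brain-Stem",
    "Optic-Chiasm",
    "WM-hypointensities",
    "non-WM-hypointensities",
    "Left-Cerebral-White-Matter", "Right-Cerebral-White-Matter",
    "Left-Cerebral-Cortex", "Right-Cerebral-Cortex",
    "Left-Lateral-Ventricle", "Right-Lateral-Ventricle",
    "Left-Inf-Lat-Vent", "Right-Inf-Lat-Vent",
    "Left-Cerebellum-White-Matter", "Right-Cerebellum-White-Matter",
    "Left-Cerebellum-Cortex", "Right-Cerebellum-Cortex",
    "Left-Thalamus-Proper", "Right-Thalamus-Proper",
    "Left-Caudate", "Right-Caudate",
    "Left-Putamen", "Right-Putamen",
    "Left-Pallidum", "Right-Pallidum",
    "Left-Hippocampus", "Right-Hippocampus",
    "Left-Amygdala", "Right-Amygdala",
    "Left-Accumbens-area", "Right-Accumbens-area",
    "Left-VentralDC", "Right-VentralDC",
    "Left-choroid-plexus", "Right-choroid-plexus"
  ],
  "func": [
    "Left-Cerebral-White-Matter", "Right-Cerebral-White-Matter",
    "Left-Cerebral-Cortex", "Right-Cerebral-Cortex",
    "Left-Inf-Lat-Vent", "Right-Inf-Lat-Vent",
    "Left-Cerebellum-White-Matter", "Right-Cerebellum-White-Matter",
    "Left-Cerebellum-Cortex", "Right-Cerebellum-Cortex",
    "Left-Thalamus-Proper", "Right-Thalamus-Proper",
    "Left-Caudate", "Right-Caudate",
    "Left-Putamen", "Right-Putamen",
    "Left-Pallidum", "Right-Pallidum",
    "Left-Hippocampus", "Right-Hippocampus",
    "Left-Amygdala", "Right-Amygdala",
    "Left-Accumbens-area", "Right-Accumbens-area",
    "Left-choroid-plexus", "Right-choroid-plexus"
  ],
  "potato": [
    "Left-Lateral-Ventricle", "Right-Lateral-Ventricle",
    "Left-Cerebral-White-Matter", "Right-Cerebral-White-Matter",
    "Left-Thalamus-Proper", "Right-Thalamus-Proper",
    "Left-Caudate", "Right-Caudate",
    "Left-Putamen", "Right-Putamen",
    "Left-Pallidum", "Right-Pallidum",
    "Left-Hippocampus", "Right-Hippocampus",
    "Left-Amygdala", "Right-Amygdala"
  ]
}
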