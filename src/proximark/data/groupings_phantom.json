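{
  "all": [
    "CSF",
    "Left-Cerebral-Cortex", "Right-Cerebral-Cortex",
    "Left-Cerebral-White-Matter", "Right-Cerebral-White-Matter",
    "Left-Lateral-Ventricle", "Right-Lateral-Ventricle",
    "Left-Thalamus-Proper", "Right-Thalamus-Proper",
    "Left-Hippocampus", "Right-Hippocampus",
    "Left-Amygdala", "Right-Amygdala",
    "Brain-Stem"
  ],
  "brain": [
    "Left-Cerebral-Cortex", "Right-Cerebral-Cortex",
    "Left-Cerebral-White-Matter", "Right-Cerebral-White-Matter",
    "Left-Lateral-Ventricle", "Right-Lateral-Ventricle",
    "Left-Thalamus-Proper", "Right-Thalamus-Proper",
    "Left-Hippocampus", "Right-Hippocampus",
    "Left-Amygdala", "Right-Amygdala",
    "Brain-Stem"
  ],
  "potato": [
    "Left-Lateral-Ventricle", "Right-Lateral-Ventricle",
    "Left-Cerebral-White-Matter", "Right-Cerebral-White-Matter",
    "Left-Thalamus-Proper", "Right-Thalamus-Proper",
    "Left-Hippocampus", "Right-Hippocampus",
    "Left-Amygdala", "Right-Amygdala"
  ]
}
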