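{
 "grid_shape": [
  64,
  64,
  64
 ],
 "spacing_mm": [
  1.0,
  1.0,
  1.0
 ],
 "rng_seed": 0,
 "regions": [
  {
   "name": "CSF",
   "label": 1,
   "center_frac": [
    0.5,
    0.5,
    0.5
   ],
   "semi_axes_frac": [
    0.46,
    0.46,
    0.46
   ]
  },
  {
   "name": "Left-Cerebral-Cortex",
   "label": 2,
   "center_frac": [
    0.3,
    0.5,
    0.55
   ],
   "semi_axes_frac": [
    0.18,
    0.38,
    0.34
   ]
  },
  {
   "name": "Right-Cerebral-Cortex",
   "label": 3,
   "center_frac": [
    0.7,
    0.5,
    0.55
   ],
   "semi_axes_frac": [
    0.18,
    0.38,
    0.34
   ]
  },
  {
   "name": "Left-Cerebral-White-Matter",
   "label": 4,
   "center_frac": [
    0.3,
    0.5,
    0.55
   ],
   "semi_axes_frac": [
    0.13,
    0.31,
    0.26
   ]
  },
  {
   "name": "Right-Cerebral-White-Matter",
   "label": 5,
   "center_frac": [
    0.7,
    0.5,
    0.55
   ],
   "semi_axes_frac": [
    0.13,
    0.31,
    0.26
   ]
  },
  {
   "name": "Left-Lateral-Ventricle",
   "label": 6,
   "center_frac": [
    0.38,
    0.48,
    0.57
   ],
   "semi_axes_frac": [
    0.05,
    0.16,
    0.08
   ]
  },
  {
   "name": "Right-Lateral-Ventricle",
   "label": 7,
   "center_frac": [
    0.62,
    0.48,
    0.57
   ],
   "semi_axes_frac": [
    0.05,
    0.16,
    0.08
   ]
  },
  {
   "name": "Left-Thalamus-Proper",
   "label": 8,
   "center_frac": [
    0.42,
    0.44,
    0.46
   ],
   "semi_axes_frac": [
    0.055,
    0.08,
    0.065
   ]
  },
  {
   "name": "Right-Thalamus-Proper",
   "label": 9,
   "center_frac": [
    0.5800000000000001,
    0.44,
    0.46
   ],
   "semi_axes_frac": [
    0.055,
    0.08,
    0.065
   ]
  },
  {
   "name": "Left-Hippocampus",
   "label": 10,
   "center_frac": [
    0.32,
    0.36,
    0.4
   ],
   "semi_axes_frac": [
    0.08,
    0.13,
    0.08
   ]
  },
  {
   "name": "Right-Hippocampus",
   "label": 11,
   "center_frac": [
    0.6799999999999999,
    0.36,
    0.4
   ],
   "semi_axes_frac": [
    0.08,
    0.13,
    0.08
   ]
  },
  {
   "name": "Left-Amygdala",
   "label": 12,
   "center_frac": [
    0.32,
    0.24,
    0.42
   ],
   "semi_axes_frac": [
    0.05,
    0.055,
    0.05
   ]
  },
  {
   "name": "Right-Amygdala",
   "label": 13,
   "center_frac": [
    0.6799999999999999,
    0.24,
    0.42
   ],
   "semi_axes_frac": [
    0.05,
    0.055,
    0.05
   ]
  },
  {
   "name": "Brain-Stem",
   "label": 14,
   "center_frac": [
    0.5,
    0.42,
    0.22
   ],
   "semi_axes_frac": [
    0.06,
    0.07,
    0.15
   ]
  }
 ],
 "atrophy": {
  "class_steps": {
   "NC": {},
   "MCI": {
    "Left-Hippocampus": -1,
    "Right-Hippocampus": -1
   },
   "AD": {
    "Left-Hippocampus": -2,
    "Right-Hippocampus": -2,
    "Left-Lateral-Ventricle": 1,
    "Right-Lateral-Ventricle": 1
   }
  },
  "m12_increment": {
   "NC": {},
   "MCI": {},
   "AD": {
    "Left-Hippocampus": -1,
    "Right-Hippocampus": -1,
    "Left-Lateral-Ventricle": 1,
    "Right-Lateral-Ventricle": 1
   }
  },
  "converter_increment_class": "AD",
  "fill_region": "CSF",
  "min_voxels": 1,
  "age_slope": 0.5,
  "age_ref": 65.0,
  "age_regions": [
   "Left-Cerebral-Cortex",
   "Right-Cerebral-Cortex"
  ]
 },
 "noise": {
  "scale_sigma": 0.03,
  "shift_max_voxels": 0.5,
  "boundary_flip_frac": 0.005,
  "age_mean": 73.0,
  "age_sd": 6.0,
  "age_range": [
   55.0,
   90.0
  ]
 }
}
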