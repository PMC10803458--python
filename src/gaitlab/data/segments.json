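{
  "description": "Default 11-segment anthropometric table (hands and feet excluded). Mass fractions follow published segmental tables for an adult body; com_position_fraction is the segment-COM position along proximal->distal. Replace this file to use a population-specific standard.",
  "segments": [
    {"name": "head", "proximal": "neck", "distal": "head", "mass_fraction": 0.081, "com_position_fraction": 0.5},
    {"name": "upper_trunk", "proximal": "neck", "distal": "thorax", "mass_fraction": 0.216, "com_position_fraction": 0.5},
    {"name": "lower_trunk", "proximal": "thorax", "distal": "sacrum", "mass_fraction": 0.281, "com_position_fraction": 0.5},
    {"name": "upper_arm_left", "proximal": "shoulder_left", "distal": "elbow_left", "mass_fraction": 0.028, "com_position_fraction": 0.5},
    {"name": "upper_arm_right", "proximal": "shoulder_right", "distal": "elbow_right", "mass_fraction": 0.028, "com_position_fraction": 0.5},
    {"name": "forearm_left", "proximal": "elbow_left", "distal": "wrist_left", "mass_fraction": 0.016, "com_position_fraction": 0.5},
    {"name": "forearm_right", "proximal": "elbow_right", "distal": "wrist_right", "mass_fraction": 0.016, "com_position_fraction": 0.5},
    {"name": "thigh_left", "proximal": "hip_left", "distal": "knee_left", "mass_fraction": 0.1, "com_position_fraction": 0.5},
    {"name": "thigh_right", "proximal": "hip_right", "distal": "knee_right", "mass_fraction": 0.1, "com_position_fraction": 0.5},
    {"name": "shank_left", "proximal": "knee_left", "distal": "ankle_left", "mass_fraction": 0.0465, "com_position_fraction": 0.5},
    {"name": "shank_right", "proximal": "knee_right", "distal": "ankle_right", "mass_fraction": 0.0465, "com_position_fraction": 0.5}
  ]
}
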