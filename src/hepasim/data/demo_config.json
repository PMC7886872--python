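{
  "tree": {
    "depth": 4,
    "root_radius_m": 0.003,
    "asymmetry": 0.8,
    "length_ratio": 8.0
  },
  "phantom": {
    "n_tumors": 3
  },
  "sim": {
    "cardiac_period_s": 1.0,
    "n_cycles": 4,
    "dt_s": 0.002
  },
  "infusions": [
    {
      "vessel_id": "v",
      "axial_fraction": 0.5,
      "radial_offset_fraction": 0.2,
      "azimuth_rad": 0.0,
      "injection_velocity_m_s": 0.52,
      "activity_gbq": 0.5,
      "n_particles": 10000,
      "catheter_inner_radius_m": 0.00025
    },
    {
      "vessel_id": "v0",
      "axial_fraction": 0.4,
      "radial_offset_fraction": 0.0,
      "azimuth_rad": 0.0,
      "injection_velocity_m_s": 0.45,
      "activity_gbq": 0.2,
      "n_particles": 10000,
      "catheter_inner_radius_m": 0.00025
    }
  ],
  "noise_sd": 2.0,
  "seed": 7
}
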