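{
  "reference_thigh_length_m": 0.413,
  "anthropometry": {
    "mass_kg": 75.8,
    "height_m": 1.74,
    "thigh_length_m": 0.413
  },
  "sigma_m_n_per_cm2": 60.0,
  "gamma": 0.2,
  "eps_t0": 0.049,
  "quad_coactivation": 0.075,
  "st_name": "semitendinosus",
  "st_morphology": {
    "acsa_max_cm2": 11.8,
    "compartment_lengths_cm": [
      20.5,
      24.5
    ],
    "l_sarc_um": 2.89
  },
  "muscles": {
    "semitendinosus": {},
    "semimembranosus": {
      "lf_o_m": 0.069,
      "alpha_o_rad": 0.26,
      "volume_regression": [
        1.7401,
        40.49
      ],
      "anatomical_norm_length": 1.04
    },
    "biceps_femoris_lh": {
      "lf_o_m": 0.098,
      "alpha_o_rad": 0.2,
      "volume_regression": [
        1.5145,
        35.25
      ],
      "anatomical_norm_length": 1.04
    },
    "biceps_femoris_sh": {
      "lf_o_m": 0.11,
      "alpha_o_rad": 0.21,
      "volume_regression": [
        0.7734,
        17.99
      ],
      "anatomical_norm_length": 1.03
    },
    "gracilis": {
      "lf_o_m": 0.228,
      "alpha_o_rad": 0.0,
      "volume_regression": [
        0.7089,
        16.5
      ],
      "anatomical_norm_length": 1.02
    },
    "sartorius": {
      "lf_o_m": 0.403,
      "alpha_o_rad": 0.0,
      "volume_regression": [
        1.0956,
        25.5
      ],
      "anatomical_norm_length": 0.98
    },
    "rectus_femoris": {
      "lf_o_m": 0.076,
      "alpha_o_rad": 0.24,
      "volume_regression": [
        1.7401,
        40.49
      ],
      "anatomical_norm_length": 0.8
    },
    "vastus_lateralis": {
      "lf_o_m": 0.099,
      "alpha_o_rad": 0.32,
      "volume_regression": [
        3.609,
        84.0
      ],
      "anatomical_norm_length": 0.8
    },
    "vastus_medialis": {
      "lf_o_m": 0.097,
      "alpha_o_rad": 0.52,
      "volume_regression": [
        2.7068,
        62.99
      ],
      "anatomical_norm_length": 0.8
    },
    "vastus_intermedius": {
      "lf_o_m": 0.099,
      "alpha_o_rad": 0.08,
      "volume_regression": [
        1.869,
        43.49
      ],
      "anatomical_norm_length": 0.8
    }
  },
  "geometry": {
    "scale": 1.0,
    "muscles": {
      "semitendinosus": {
        "arm_coeffs_m_per_deg": [
          0.031000000000000017,
          0.00013888888888888905,
          1.1111111111111066e-06,
          -6.172839506172803e-09
        ],
        "l_mtu_ref_m": 0.465,
        "hip_arm_m": 0.065,
        "action": "flexor"
      },
      "semimembranosus": {
        "arm_coeffs_m_per_deg": [
          0.023000000000000003,
          0.0002388888888888893,
          5.555555555555509e-07,
          -2.4691358024691336e-08
        ],
        "l_mtu_ref_m": 0.44,
        "hip_arm_m": 0.065,
        "action": "flexor"
      },
      "biceps_femoris_lh": {
        "arm_coeffs_m_per_deg": [
          0.019,
          0.000272222222222223,
          5.555555555555371e-07,
          -2.4691358024691236e-08
        ],
        "l_mtu_ref_m": 0.43,
        "hip_arm_m": 0.06,
        "action": "flexor"
      },
      "biceps_femoris_sh": {
        "arm_coeffs_m_per_deg": [
          0.013999999999999997,
          0.00036111111111111164,
          -2.2222222222222348e-06,
          6.172839506172947e-09
        ],
        "l_mtu_ref_m": 0.26,
        "hip_arm_m": 0.0,
        "action": "flexor"
      },
      "gracilis": {
        "arm_coeffs_m_per_deg": [
          0.016000000000000004,
          0.0003722222222222228,
          -2.7777777777777927e-06,
          1.2345679012345808e-08
        ],
        "l_mtu_ref_m": 0.37,
        "hip_arm_m": 0.02,
        "action": "flexor"
      },
      "sartorius": {
        "arm_coeffs_m_per_deg": [
          0.008999999999999992,
          0.0003000000000000005,
          -2.7777777777777885e-06,
          1.851851851851862e-08
        ],
        "l_mtu_ref_m": 0.52,
        "hip_arm_m": -0.03,
        "action": "flexor"
      },
      "rectus_femoris": {
        "arm_coeffs_m_per_deg": [
          0.033,
          0.0002777777777777782,
          -3.888888888888893e-06,
          6.172839506172841e-09
        ],
        "l_mtu_ref_m": 0.41,
        "hip_arm_m": -0.04,
        "action": "extensor"
      },
      "vastus_lateralis": {
        "arm_coeffs_m_per_deg": [
          0.033,
          0.0002777777777777782,
          -3.888888888888893e-06,
          6.172839506172841e-09
        ],
        "l_mtu_ref_m": 0.22,
        "hip_arm_m": 0.0,
        "action": "extensor"
      },
      "vastus_medialis": {
        "arm_coeffs_m_per_deg": [
          0.033,
          0.0002777777777777782,
          -3.888888888888893e-06,
          6.172839506172841e-09
        ],
        "l_mtu_ref_m": 0.21,
        "hip_arm_m": 0.0,
        "action": "extensor"
      },
      "vastus_intermedius": {
        "arm_coeffs_m_per_deg": [
          0.033,
          0.0002777777777777782,
          -3.888888888888893e-06,
          6.172839506172841e-09
        ],
        "l_mtu_ref_m": 0.23,
        "hip_arm_m": 0.0,
        "action": "extensor"
      }
    }
  }
}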