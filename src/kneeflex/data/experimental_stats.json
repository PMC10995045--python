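{
  "regenerated": {
    "n": 7,
    "angles": {
      "15": {"contra_mean_nm": 102.2, "contra_sd_nm": 32.2, "aclr_mean_nm": 99.8, "aclr_sd_nm": 33.7, "diff_mean": -0.020, "diff_sd": 0.109},
      "45": {"contra_mean_nm": 88.0, "contra_sd_nm": 29.6, "aclr_mean_nm": 80.8, "aclr_sd_nm": 19.5, "diff_mean": -0.053, "diff_sd": 0.119},
      "60": {"contra_mean_nm": 83.2, "contra_sd_nm": 26.5, "aclr_mean_nm": 66.6, "aclr_sd_nm": 19.1, "diff_mean": -0.187, "diff_sd": 0.105},
      "90": {"contra_mean_nm": 63.5, "contra_sd_nm": 18.3, "aclr_mean_nm": 42.9, "aclr_sd_nm": 12.7, "diff_mean": -0.321, "diff_sd": 0.079}
    }
  },
  "total": {
    "n": 10,
    "angles": {
      "15": {"contra_mean_nm": 87.4, "contra_sd_nm": 35.8, "aclr_mean_nm": 83.2, "aclr_sd_nm": 38.5, "diff_mean": -0.058, "diff_sd": 0.095},
      "45": {"contra_mean_nm": 77.0, "contra_sd_nm": 30.2, "aclr_mean_nm": 68.9, "aclr_sd_nm": 25.2, "diff_mean": -0.097, "diff_sd": 0.098},
      "60": {"contra_mean_nm": 71.6, "contra_sd_nm": 28.8, "aclr_mean_nm": 56.2, "aclr_sd_nm": 23.1, "diff_mean": -0.217, "diff_sd": 0.076},
      "90": {"contra_mean_nm": 55.6, "contra_sd_nm": 19.8, "aclr_mean_nm": 37.4, "aclr_sd_nm": 13.7, "diff_mean": -0.324, "diff_sd": 0.062}
    }
  }
}
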