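{
  "rate_constants": {
    "k0": 0.3228,
    "k1": 0.03342,
    "k2": 5.755,
    "k3": 19.82,
    "k4": 0.08575
  },
  "experiment": {
    "P0": 23.0,
    "U0": 4.1,
    "buffer": "200 mM MES pH 5.3",
    "temperature_C": 25.0
  },
  "phase": {
    "A_crit_mM": 0.9,
    "fuel_lower_mM": 7.5,
    "metastable_anchors": [[1.4, 25.0], [4.1, 40.0]]
  },
  "charges": {
    "product": 3,
    "precursor": 1,
    "rna_monomer": -1,
    "include_precursor": false
  },
  "mass_balance": {
    "dynamic": {
      "fuel_mM": 25.0,
      "filtrate_A_mM": 1.7,
      "volume_fraction": 0.0014,
      "rna_droplet_fraction": 0.9
    },
    "metastable": {
      "fuel_mM": 60.0,
      "filtrate_A_mM": 3.9,
      "volume_fraction": 0.0015,
      "rna_droplet_fraction": 1.0
    }
  },
  "detection": {
    "hplc_limit_mM": 0.1,
    "turbidity_cutoff_au": 0.01
  },
  "turbidity": {
    "scale_au_per_mM": 0.25,
    "metastable_persistence_min": 76.0
  },
  "itc_design": {
    "cell_volume_uL": 250.0,
    "cell_rna_mM": 1.1,
    "syringe_peptide_mM": 38.0,
    "n_injections": 26,
    "injection_volume_uL": 1.5
  }
}
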