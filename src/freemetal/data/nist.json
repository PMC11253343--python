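{
  "source": "NIST",
  "citation": "Representative critically-selected stability constants (NIST-style critical tables lineage), log10 association constants at 20 C, 100 mM ionic equivalence.",
  "metals": [
    {"id": "Ca", "charge": 2},
    {"id": "Mg", "charge": 2},
    {"id": "Zn", "charge": 2}
  ],
  "ligands": [
    {
      "id": "EGTA",
      "charge": -4,
      "ref_temperature_c": 20.0,
      "ref_ionic_equivalence_mm": 100.0,
      "protonation": [
        {"step": 1, "log_k": 9.40, "delta_h_kj_mol": -23.4},
        {"step": 2, "log_k": 8.78, "delta_h_kj_mol": -21.3},
        {"step": 3, "log_k": 2.66, "delta_h_kj_mol": null},
        {"step": 4, "log_k": 2.00, "delta_h_kj_mol": null}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 10.86, "delta_h_kj_mol": -33.1},
        {"metal": "Ca", "protons": 1, "log_k": 3.79, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 5.28, "delta_h_kj_mol": 21.3},
        {"metal": "Mg", "protons": 1, "log_k": 3.37, "delta_h_kj_mol": null},
        {"metal": "Zn", "protons": 0, "log_k": 12.60, "delta_h_kj_mol": -17.6},
        {"metal": "Zn", "protons": 1, "log_k": 5.20, "delta_h_kj_mol": null}
      ]
    },
    {
      "id": "EDTA",
      "charge": -4,
      "ref_temperature_c": 20.0,
      "ref_ionic_equivalence_mm": 100.0,
      "protonation": [
        {"step": 1, "log_k": 10.17, "delta_h_kj_mol": -23.4},
        {"step": 2, "log_k": 6.11, "delta_h_kj_mol": -17.6},
        {"step": 3, "log_k": 2.68, "delta_h_kj_mol": null},
        {"step": 4, "log_k": 2.00, "delta_h_kj_mol": null}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 10.61, "delta_h_kj_mol": -27.2},
        {"metal": "Ca", "protons": 1, "log_k": 3.52, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 8.79, "delta_h_kj_mol": 13.8},
        {"metal": "Mg", "protons": 1, "log_k": 2.28, "delta_h_kj_mol": null},
        {"metal": "Zn", "protons": 0, "log_k": 16.50, "delta_h_kj_mol": -20.1},
        {"metal": "Zn", "protons": 1, "log_k": 3.00, "delta_h_kj_mol": null}
      ]
    },
    {
      "id": "ATP",
      "charge": -4,
      "ref_temperature_c": 20.0,
      "ref_ionic_equivalence_mm": 100.0,
      "protonation": [
        {"step": 1, "log_k": 6.48, "delta_h_kj_mol": -5.0},
        {"step": 2, "log_k": 4.00, "delta_h_kj_mol": -3.0}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 3.91, "delta_h_kj_mol": 2.0},
        {"metal": "Ca", "protons": 1, "log_k": 1.80, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 4.22, "delta_h_kj_mol": 18.0},
        {"metal": "Mg", "protons": 1, "log_k": 2.24, "delta_h_kj_mol": null},
        {"metal": "Zn", "protons": 0, "log_k": 5.21, "delta_h_kj_mol": 8.0},
        {"metal": "Zn", "protons": 1, "log_k": 2.70, "delta_h_kj_mol": null}
      ]
    }
  ]
}
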