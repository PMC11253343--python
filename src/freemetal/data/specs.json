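{
  "source": "SPECS",
  "citation": "Representative values in the lineage of the SPECS program (Fabiato, Methods Enzymol 1988), log10 association constants at 20 C, 100 mM ionic equivalence.",
  "metals": [
    {"id": "Ca", "charge": 2},
    {"id": "Mg", "charge": 2}
  ],
  "ligands": [
    {
      "id": "EGTA",
      "charge": -4,
      "ref_temperature_c": 20.0,
      "ref_ionic_equivalence_mm": 100.0,
      "protonation": [
        {"step": 1, "log_k": 9.43, "delta_h_kj_mol": -23.4},
        {"step": 2, "log_k": 8.79, "delta_h_kj_mol": -21.3},
        {"step": 3, "log_k": 2.65, "delta_h_kj_mol": null},
        {"step": 4, "log_k": 2.00, "delta_h_kj_mol": null}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 10.72, "delta_h_kj_mol": -33.1},
        {"metal": "Ca", "protons": 1, "log_k": 3.80, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 5.17, "delta_h_kj_mol": 21.3},
        {"metal": "Mg", "protons": 1, "log_k": 3.35, "delta_h_kj_mol": null}
      ]
    },
    {
      "id": "EDTA",
      "charge": -4,
      "ref_temperature_c": 20.0,
      "ref_ionic_equivalence_mm": 100.0,
      "protonation": [
        {"step": 1, "log_k": 10.19, "delta_h_kj_mol": -23.4},
        {"step": 2, "log_k": 6.13, "delta_h_kj_mol": -17.6},
        {"step": 3, "log_k": 2.69, "delta_h_kj_mol": null},
        {"step": 4, "log_k": 2.00, "delta_h_kj_mol": null}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 10.56, "delta_h_kj_mol": -27.2},
        {"metal": "Ca", "protons": 1, "log_k": 3.50, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 8.65, "delta_h_kj_mol": 13.8},
        {"metal": "Mg", "protons": 1, "log_k": 2.26, "delta_h_kj_mol": null}
      ]
    },
    {
      "id": "ATP",
      "charge": -4,
      "ref_temperature_c": 20.0,
      "ref_ionic_equivalence_mm": 100.0,
      "protonation": [
        {"step": 1, "log_k": 6.49, "delta_h_kj_mol": -5.0},
        {"step": 2, "log_k": 3.95, "delta_h_kj_mol": -3.0}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 3.70, "delta_h_kj_mol": 2.0},
        {"metal": "Ca", "protons": 1, "log_k": 1.75, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 4.00, "delta_h_kj_mol": 18.0},
        {"metal": "Mg", "protons": 1, "log_k": 2.12, "delta_h_kj_mol": null}
      ]
    }
  ]
}
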