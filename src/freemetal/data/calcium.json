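{
  "source": "Calcium",
  "citation": "Representative values in the lineage of the Calcium program (Foehr et al., Methods Enzymol 1993; Martell & Smith tables), log10 association constants at 20 C, 100 mM ionic equivalence.",
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
        {"step": 1, "log_k": 9.46, "delta_h_kj_mol": -23.4},
        {"step": 2, "log_k": 8.85, "delta_h_kj_mol": -21.3},
        {"step": 3, "log_k": 2.68, "delta_h_kj_mol": null},
        {"step": 4, "log_k": 2.00, "delta_h_kj_mol": null}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 10.88, "delta_h_kj_mol": -33.1},
        {"metal": "Ca", "protons": 1, "log_k": 3.83, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 5.28, "delta_h_kj_mol": 21.3},
        {"metal": "Mg", "protons": 1, "log_k": 3.37, "delta_h_kj_mol": null}
      ]
    },
    {
      "id": "EDTA",
      "charge": -4,
      "ref_temperature_c": 20.0,
      "ref_ionic_equivalence_mm": 100.0,
      "protonation": [
        {"step": 1, "log_k": 10.23, "delta_h_kj_mol": -23.4},
        {"step": 2, "log_k": 6.13, "delta_h_kj_mol": -17.6},
        {"step": 3, "log_k": 2.69, "delta_h_kj_mol": null},
        {"step": 4, "log_k": 2.00, "delta_h_kj_mol": null}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 10.65, "delta_h_kj_mol": -27.2},
        {"metal": "Ca", "protons": 1, "log_k": 3.53, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 8.83, "delta_h_kj_mol": 13.8},
        {"metal": "Mg", "protons": 1, "log_k": 2.30, "delta_h_kj_mol": null}
      ]
    },
    {
      "id": "ATP",
      "charge": -4,
      "ref_temperature_c": 20.0,
      "ref_ionic_equivalence_mm": 100.0,
      "protonation": [
        {"step": 1, "log_k": 6.47, "delta_h_kj_mol": -5.0},
        {"step": 2, "log_k": 4.02, "delta_h_kj_mol": -3.0}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 3.89, "delta_h_kj_mol": 2.0},
        {"metal": "Ca", "protons": 1, "log_k": 1.80, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 4.19, "delta_h_kj_mol": 18.0},
        {"metal": "Mg", "protons": 1, "log_k": 2.22, "delta_h_kj_mol": null}
      ]
    }
  ]
}
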