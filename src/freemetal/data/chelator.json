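{
  "source": "Chelator",
  "citation": "Representative values in the lineage of the Chelator program (Schoenmakers et al., BioTechniques 1992), log10 association constants at 20 C, 100 mM ionic equivalence.",
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
        {"step": 1, "log_k": 9.47, "delta_h_kj_mol": -23.4},
        {"step": 2, "log_k": 8.85, "delta_h_kj_mol": -21.3},
        {"step": 3, "log_k": 2.66, "delta_h_kj_mol": null},
        {"step": 4, "log_k": 2.00, "delta_h_kj_mol": null}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 10.97, "delta_h_kj_mol": -33.1},
        {"metal": "Ca", "protons": 1, "log_k": 3.85, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 5.21, "delta_h_kj_mol": 21.3},
        {"metal": "Mg", "protons": 1, "log_k": 3.37, "delta_h_kj_mol": null}
      ]
    },
    {
      "id": "EDTA",
      "charge": -4,
      "ref_temperature_c": 20.0,
      "ref_ionic_equivalence_mm": 100.0,
      "protonation": [
        {"step": 1, "log_k": 10.26, "delta_h_kj_mol": -23.4},
        {"step": 2, "log_k": 6.16, "delta_h_kj_mol": -17.6},
        {"step": 3, "log_k": 2.67, "delta_h_kj_mol": null},
        {"step": 4, "log_k": 2.00, "delta_h_kj_mol": null}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 10.70, "delta_h_kj_mol": -27.2},
        {"metal": "Ca", "protons": 1, "log_k": 3.51, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 8.69, "delta_h_kj_mol": 13.8},
        {"metal": "Mg", "protons": 1, "log_k": 2.28, "delta_h_kj_mol": null}
      ]
    },
    {
      "id": "ATP",
      "charge": -4,
      "ref_temperature_c": 20.0,
      "ref_ionic_equivalence_mm": 100.0,
      "protonation": [
        {"step": 1, "log_k": 6.51, "delta_h_kj_mol": -5.0},
        {"step": 2, "log_k": 4.05, "delta_h_kj_mol": -3.0}
      ],
      "complexes": [
        {"metal": "Ca", "protons": 0, "log_k": 3.77, "delta_h_kj_mol": 2.0},
        {"metal": "Ca", "protons": 1, "log_k": 1.78, "delta_h_kj_mol": null},
        {"metal": "Mg", "protons": 0, "log_k": 4.06, "delta_h_kj_mol": 18.0},
        {"metal": "Mg", "protons": 1, "log_k": 2.17, "delta_h_kj_mol": null}
      ]
    }
  ]
}
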