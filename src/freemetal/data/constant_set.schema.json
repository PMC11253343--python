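{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "freemetal constant-set interchange format",
  "description": "A named library of metal and chelator records with absolute log10 ASSOCIATION constants (molar basis) at the record's reference temperature (degrees C) and ionic equivalence (mM). Protonation constants are STEPWISE: step 1 adds the first proton to the fully deprotonated ligand. A complex with protons = n forms from free metal plus the ligand form carrying n protons (protons = 1 is M + HL = MHL). delta_h_kj_mol is the association enthalpy, exothermic negative; null or absent suppresses temperature correction for that constant. Unknown extra keys are preserved on round trip but ignored by computation.",
  "type": "object",
  "required": ["metals", "ligands"],
  "properties": {
    "source": {"type": "string"},
    "citation": {"type": "string"},
    "metals": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "charge"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "charge": {"type": "integer", "minimum": 1, "maximum": 3}
        }
      }
    },
    "ligands": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "charge", "ref_temperature_c", "ref_ionic_equivalence_mm"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "charge": {"type": "integer"},
          "ref_temperature_c": {"type": "number"},
          "ref_ionic_equivalence_mm": {"type": "number", "exclusiveMinimum": 0},
          "protonation": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["step", "log_k"],
              "properties": {
                "step": {"type": "integer", "minimum": 1, "maximum": 4},
                "log_k": {"type": "number"},
                "delta_h_kj_mol": {"type": ["number", "null"]}
              }
            }
          },
          "complexes": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["metal", "protons", "log_k"],
              "properties": {
                "metal": {"type": "string", "minLength": 1},
                "protons": {"type": "integer", "minimum": 0},
                "log_k": {"type": "number"},
                "delta_h_kj_mol": {"type": ["number", "null"]}
              }
            }
          }
        }
      }
    }
  }
}
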