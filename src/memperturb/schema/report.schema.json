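{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "memperturb run report",
  "type": "object",
  "required": ["package", "version", "seed", "config", "stages"],
  "properties": {
    "package": {"type": "string", "const": "memperturb"},
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "stages": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "error": {"type": "string"}
        }
      },
      "properties": {
        "events": {
          "type": "object",
          "properties": {
            "expulsions": {"type": "integer"},
            "flipflops": {"type": "integer"},
            "pbc_crossings": {"type": "integer"},
            "n_pe": {"type": "integer"},
            "final_remaining": {"type": "integer"}
          }
        },
        "structure": {
          "type": "object",
          "properties": {
            "apl_nm2_mean": {"type": "number"},
            "apl_nm2_sd": {"type": "number"},
            "thickness_pp_nm_mean": {"type": "number"},
            "thickness_pp_nm_sd": {"type": "number"},
            "leaflet_thickness_nm_mean": {"type": "number"}
          }
        },
        "order": {"type": "object"},
        "diffusion": {
          "type": "object",
          "properties": {
            "D_nm2_ns": {"type": "number"},
            "D_se": {"type": "number"}
          }
        },
        "water": {
          "type": "object",
          "properties": {
            "per_lipid_mean": {"type": "number"},
            "per_lipid_sd": {"type": "number"}
          }
        },
        "contacts": {"type": "object"},
        "free_energy": {
          "type": "object",
          "properties": {
            "delta_g_kcal_mol": {"type": "number"},
            "min_location_nm": {"type": "number"},
            "co_over_ci": {"type": "number"},
            "convention": {"type": "string"}
          }
        }
      }
    }
  }
}
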