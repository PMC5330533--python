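{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "kinfer pipeline report",
  "type": "object",
  "required": ["identification", "classification", "scheme", "trajectory", "provenance"],
  "properties": {
    "identification": {
      "type": "object",
      "required": ["G", "tau_poles", "tau_zeros", "dc_gain", "loss", "lambda_hat"],
      "properties": {
        "G": {
          "type": "object",
          "required": ["zeros", "poles", "gain"],
          "properties": {
            "zeros": {"type": "array", "items": {"type": "number"}},
            "poles": {"type": "array", "items": {"type": "number"}},
            "gain": {"type": "number"}
          }
        },
        "tau_poles": {"type": "array", "items": {"type": "number"}},
        "tau_zeros": {"type": "array", "items": {"type": "number"}},
        "dc_gain": {"type": "number"},
        "loss": {"type": "number"},
        "sim_loss": {"type": "number"},
        "lambda_hat": {"type": "number"},
        "arx_orders": {"type": "array", "items": {"type": "number"}}
      }
    },
    "classification": {
      "type": "object",
      "required": ["configuration", "ambiguous"],
      "properties": {
        "configuration": {"type": "string"},
        "f_valp": {"type": "number"},
        "f_valf": {"type": "number"},
        "recovered": {
          "type": "object",
          "properties": {
            "k_a": {"type": "number"}, "k_b": {"type": "number"},
            "tau_a": {"type": "number"}, "tau_b": {"type": "number"}
          }
        }
      }
    },
    "scheme": {
      "type": "object",
      "properties": {
        "configuration": {"type": "string"},
        "states": {"type": "array", "items": {"type": "string"}},
        "observable": {"type": "string"},
        "input_state": {"type": "string"},
        "transitions": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["from", "to", "sigma"],
            "properties": {
              "from": {"type": "string"}, "to": {"type": "string"},
              "sigma": {"type": "number"}
            }
          }
        },
        "gamma": {"type": "number"},
        "obs_scale": {"type": "number"},
        "sigma": {"type": "object"}
      }
    },
    "trajectory": {
      "type": "object",
      "properties": {
        "relative_rms_misfit": {"type": "number"},
        "y_final": {"type": "number"},
        "occupancy_final": {"type": "object"}
      }
    },
    "trace_snr_db": {"type": "number"},
    "provenance": {
      "type": "object",
      "required": ["package", "version", "config_hash"],
      "properties": {
        "package": {"type": "string"},
        "version": {"type": "string"},
        "config_hash": {"type": "string"},
        "classify_seed": {"type": "number"},
        "n_samples": {"type": "number"},
        "Ts": {"type": "number"}
      }
    }
  }
}
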