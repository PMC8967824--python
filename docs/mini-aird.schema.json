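{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "mini-Aird run metadata",
 "type": "object",
 "required": ["format_version", "precision", "acquisition_mode", "total_spectra", "blocks"],
 "properties": {
  "format_version": {"const": "mini-aird-1"},
  "precision": {
   "type": "object",
   "required": ["decimal_places"],
   "properties": {
    "decimal_places": {"enum": [4, 5, 6]},
    "scale": {"enum": [10000, 100000, 1000000]}
   }
  },
  "acquisition_mode": {"enum": ["DDA", "DIA"]},
  "source": {"type": "object"},
  "total_spectra": {"type": "integer", "minimum": 0},
  "binary_file": {"type": "string"},
  "blocks": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["block_id", "ms_level", "layer_exponent", "stacks"],
    "properties": {
     "block_id": {"type": "integer", "minimum": 0},
     "ms_level": {"enum": [1, 2]},
     "layer_exponent": {"type": "integer", "minimum": 0, "maximum": 16},
     "precursor_window": {
      "oneOf": [
       {"type": "null"},
       {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}
      ]
     },
     "stacks": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["offset", "mz_bytes", "tag_bytes", "intensity_bytes",
                    "layer_exponent", "spectrum_count", "peaks_per_layer",
                    "rt", "spectrum_ids"],
       "properties": {
        "offset": {"type": "integer", "minimum": 0},
        "mz_bytes": {"type": "integer", "minimum": 0},
        "tag_bytes": {"type": "integer", "minimum": 0},
        "intensity_bytes": {"type": "integer", "minimum": 0},
        "layer_exponent": {"type": "integer", "minimum": 0, "maximum": 16},
        "spectrum_count": {"type": "integer", "minimum": 1},
        "peaks_per_layer": {"type": "array", "items": {"type": "integer", "minimum": 0}},
        "intensity_width": {"enum": [32, 64]},
        "rt": {"type": "array", "items": {"type": "number", "minimum": 0}},
        "spectrum_ids": {"type": "array", "items": {"type": "integer", "minimum": 0}},
        "precursor_window": {
         "oneOf": [
          {"type": "null"},
          {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}
         ]
        }
       }
      }
     }
    }
   }
  }
 }
}
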