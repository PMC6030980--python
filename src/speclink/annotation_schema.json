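{
 "$defs": {
  "FragmentModel": {
   "properties": {
    "charge": {
     "title": "Charge",
     "type": "integer"
    },
    "contains_link": {
     "default": false,
     "title": "Contains Link",
     "type": "boolean"
    },
    "end": {
     "default": 1,
     "title": "End",
     "type": "integer"
    },
    "index": {
     "title": "Index",
     "type": "integer"
    },
    "label": {
     "default": "",
     "title": "Label",
     "type": "string"
    },
    "loss": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Loss"
    },
    "mz": {
     "title": "Mz",
     "type": "number"
    },
    "neutral_mass": {
     "title": "Neutral Mass",
     "type": "number"
    },
    "peptide_id": {
     "title": "Peptide Id",
     "type": "string"
    },
    "series": {
     "title": "Series",
     "type": "string"
    },
    "start": {
     "default": 1,
     "title": "Start",
     "type": "integer"
    }
   },
   "required": [
    "series",
    "index",
    "peptide_id",
    "charge",
    "neutral_mass",
    "mz"
   ],
   "title": "FragmentModel",
   "type": "object"
  },
  "MatchModel": {
   "properties": {
    "error_da": {
     "title": "Error Da",
     "type": "number"
    },
    "error_ppm": {
     "title": "Error Ppm",
     "type": "number"
    },
    "fragment_index": {
     "title": "Fragment Index",
     "type": "integer"
    },
    "isotope_peak": {
     "title": "Isotope Peak",
     "type": "integer"
    },
    "peak_index": {
     "title": "Peak Index",
     "type": "integer"
    }
   },
   "required": [
    "peak_index",
    "fragment_index",
    "isotope_peak",
    "error_da",
    "error_ppm"
   ],
   "title": "MatchModel",
   "type": "object"
  },
  "ModModel": {
   "properties": {
    "mass_delta": {
     "title": "Mass Delta",
     "type": "number"
    },
    "name": {
     "title": "Name",
     "type": "string"
    },
    "position": {
     "title": "Position",
     "type": "integer"
    }
   },
   "required": [
    "position",
    "name",
    "mass_delta"
   ],
   "title": "ModModel",
   "type": "object"
  },
  "PeakModel": {
   "properties": {
    "intensity": {
     "title": "Intensity",
     "type": "number"
    },
    "mz": {
     "title": "Mz",
     "type": "number"
    }
   },
   "required": [
    "mz",
    "intensity"
   ],
   "title": "PeakModel",
   "type": "object"
  },
  "PeptideModel": {
   "properties": {
    "link_position": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Link Position"
    },
    "mods": {
     "items": {
      "$ref": "#/$defs/ModModel"
     },
     "title": "Mods",
     "type": "array"
    },
    "sequence": {
     "title": "Sequence",
     "type": "string"
    }
   },
   "required": [
    "sequence"
   ],
   "title": "PeptideModel",
   "type": "object"
  },
  "PrecursorModel": {
   "properties": {
    "charge": {
     "title": "Charge",
     "type": "integer"
    },
    "mz": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Mz"
    }
   },
   "required": [
    "charge"
   ],
   "title": "PrecursorModel",
   "type": "object"
  },
  "SettingsModel": {
   "properties": {
    "ion_types": {
     "items": {
      "type": "string"
     },
     "title": "Ion Types",
     "type": "array"
    },
    "losses_enabled": {
     "title": "Losses Enabled",
     "type": "boolean"
    },
    "max_fragment_charge": {
     "title": "Max Fragment Charge",
     "type": "integer"
    },
    "tolerance_unit": {
     "title": "Tolerance Unit",
     "type": "string"
    },
    "tolerance_value": {
     "title": "Tolerance Value",
     "type": "number"
    },
    "z_radical": {
     "title": "Z Radical",
     "type": "boolean"
    }
   },
   "required": [
    "tolerance_value",
    "tolerance_unit",
    "ion_types",
    "max_fragment_charge",
    "losses_enabled",
    "z_radical"
   ],
   "title": "SettingsModel",
   "type": "object"
  }
 },
 "description": "The versioned annotation JSON: everything needed to re-render the\nannotated spectrum, fragmentation key and QC plots without recomputation.",
 "properties": {
  "crosslinker_mass": {
   "anyOf": [
    {
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Crosslinker Mass"
  },
  "fragments": {
   "items": {
    "$ref": "#/$defs/FragmentModel"
   },
   "title": "Fragments",
   "type": "array"
  },
  "matches": {
   "items": {
    "$ref": "#/$defs/MatchModel"
   },
   "title": "Matches",
   "type": "array"
  },
  "peaks": {
   "items": {
    "$ref": "#/$defs/PeakModel"
   },
   "title": "Peaks",
   "type": "array"
  },
  "peptides": {
   "items": {
    "$ref": "#/$defs/PeptideModel"
   },
   "title": "Peptides",
   "type": "array"
  },
  "precursor": {
   "$ref": "#/$defs/PrecursorModel"
  },
  "schema_version": {
   "default": "1.0",
   "title": "Schema Version",
   "type": "string"
  },
  "settings": {
   "$ref": "#/$defs/SettingsModel"
  },
  "spectrum_source": {
   "additionalProperties": true,
   "title": "Spectrum Source",
   "type": "object"
  }
 },
 "required": [
  "peptides",
  "precursor",
  "settings",
  "peaks",
  "fragments",
  "matches"
 ],
 "title": "AnnotationDocument",
 "type": "object"
}
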