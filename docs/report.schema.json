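{
 "$defs": {
  "BaitEntry": {
   "properties": {
    "mol_id": {
     "title": "Mol Id",
     "type": "string"
    },
    "tc": {
     "title": "Tc",
     "type": "number"
    },
    "pharmacophore_score": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Pharmacophore Score"
    }
   },
   "required": [
    "mol_id",
    "tc"
   ],
   "title": "BaitEntry",
   "type": "object"
  },
  "FragmentEntry": {
   "properties": {
    "fragment_key": {
     "title": "Fragment Key",
     "type": "string"
    },
    "count": {
     "title": "Count",
     "type": "integer"
    },
    "rank": {
     "title": "Rank",
     "type": "integer"
    }
   },
   "required": [
    "fragment_key",
    "count",
    "rank"
   ],
   "title": "FragmentEntry",
   "type": "object"
  },
  "TargetEntry": {
   "properties": {
    "target_id": {
     "title": "Target Id",
     "type": "string"
    },
    "score": {
     "title": "Score",
     "type": "number"
    },
    "affinity": {
     "title": "Affinity",
     "type": "number"
    },
    "confidence": {
     "title": "Confidence",
     "type": "string"
    },
    "n_assays": {
     "title": "N Assays",
     "type": "integer"
    },
    "n_baits": {
     "title": "N Baits",
     "type": "integer"
    },
    "best_tc": {
     "title": "Best Tc",
     "type": "number"
    },
    "supporting_baits": {
     "items": {
      "type": "string"
     },
     "title": "Supporting Baits",
     "type": "array"
    }
   },
   "required": [
    "target_id",
    "score",
    "affinity",
    "confidence",
    "n_assays",
    "n_baits",
    "best_tc",
    "supporting_baits"
   ],
   "title": "TargetEntry",
   "type": "object"
  }
 },
 "properties": {
  "query_id": {
   "title": "Query Id",
   "type": "string"
  },
  "config": {
   "additionalProperties": true,
   "title": "Config",
   "type": "object"
  },
  "compounds": {
   "items": {
    "$ref": "#/$defs/BaitEntry"
   },
   "title": "Compounds",
   "type": "array"
  },
  "targets": {
   "items": {
    "$ref": "#/$defs/TargetEntry"
   },
   "title": "Targets",
   "type": "array"
  },
  "fragments": {
   "items": {
    "$ref": "#/$defs/FragmentEntry"
   },
   "title": "Fragments",
   "type": "array"
  },
  "notices": {
   "items": {
    "type": "string"
   },
   "title": "Notices",
   "type": "array"
  }
 },
 "required": [
  "query_id",
  "config",
  "compounds",
  "targets",
  "fragments",
  "notices"
 ],
 "title": "PipelineReport",
 "type": "object"
}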