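{
 "description": "Machine-readable pipeline summary (the shipped report schema).",
 "properties": {
  "bic_by_k": {
   "additionalProperties": {
    "type": "number"
   },
   "title": "Bic By K",
   "type": "object"
  },
  "branch_order_heads": {
   "additionalProperties": {
    "items": {
     "type": "string"
    },
    "type": "array"
   },
   "title": "Branch Order Heads",
   "type": "object"
  },
  "composition_percent": {
   "additionalProperties": {
    "additionalProperties": {
     "type": "number"
    },
    "type": "object"
   },
   "title": "Composition Percent",
   "type": "object"
  },
  "n_curated_cnv_regions": {
   "title": "N Curated Cnv Regions",
   "type": "integer"
  },
  "n_samples": {
   "title": "N Samples",
   "type": "integer"
  },
  "n_unique_variants": {
   "title": "N Unique Variants",
   "type": "integer"
  },
  "newick": {
   "title": "Newick",
   "type": "string"
  },
  "seed": {
   "title": "Seed",
   "type": "integer"
  },
  "selected_k": {
   "title": "Selected K",
   "type": "integer"
  },
  "tmb_per_sample": {
   "additionalProperties": {
    "type": "number"
   },
   "title": "Tmb Per Sample",
   "type": "object"
  },
  "total_calls": {
   "title": "Total Calls",
   "type": "integer"
  }
 },
 "required": [
  "seed",
  "n_samples",
  "n_unique_variants",
  "total_calls",
  "tmb_per_sample",
  "newick",
  "selected_k",
  "bic_by_k",
  "composition_percent",
  "n_curated_cnv_regions",
  "branch_order_heads"
 ],
 "title": "ReportSummary",
 "type": "object"
}
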