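{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "earlife participant-level count table (wide layout)",
  "description": "One row per participant, or per participant x weekend stratum when a 'stratum' column is present. Per-behavior counts use the column pair <behavior>_k (occurrences) and <behavior>_n (eligible clips). Unknown columns are preserved on read. CSV or TSV, chosen by file extension.",
  "type": "object",
  "required": ["participant_id"],
  "properties": {
    "participant_id": {
      "description": "Unique participant identifier.",
      "type": ["integer", "string"]
    },
    "stratum": {
      "description": "Optional weekend stratum label; omitted for pooled tables.",
      "enum": ["weekday", "weekend", "pooled"]
    },
    "alhb": {
      "description": "Standardized trait composite (mean of seven scale z-scores, re-standardized).",
      "type": "number"
    },
    "sex": {
      "description": "0 = male, 1 = female.",
      "enum": [0, 1]
    },
    "enrolled_in_classes": {
      "description": "False drops this participant from class-attendance analyses.",
      "type": "boolean"
    },
    "sleep_data_available": {
      "description": "False drops this participant from daytime-sleeping analyses.",
      "type": "boolean"
    }
  },
  "patternProperties": {
    "^.+_k$": {
      "description": "Occurrence count for one behavior; 0 <= k <= matching n.",
      "type": "integer",
      "minimum": 0
    },
    "^.+_n$": {
      "description": "Eligible (compliant, denominator-satisfying, codable) clip count for one behavior.",
      "type": "integer",
      "minimum": 0
    }
  }
}
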