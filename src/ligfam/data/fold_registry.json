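{
  "schema_version": "1.0",
  "description": "Registry of the 18 SAM/SAH-binding fold types (I-XVIII): 9 MTase folds and 9 non-MTase folds. Folds I-V carry their established class names; the remaining entries are placeholders named by numeral, since only the MTase/non-MTase split and the counts are load-bearing for classification.",
  "entries": [
    {"numeral": "I",     "name": "Rossmann fold (SAM-dependent MTase)", "is_mtase": true},
    {"numeral": "II",    "name": "Class II MTase (MetH reactivation-like)", "is_mtase": true},
    {"numeral": "III",   "name": "Tetrapyrrole methylase fold", "is_mtase": true},
    {"numeral": "IV",    "name": "Knotted RNA MTase (SPOUT) fold", "is_mtase": true},
    {"numeral": "V",     "name": "SET domain (beta-clip) fold", "is_mtase": true},
    {"numeral": "VI",    "name": "MTase fold VI", "is_mtase": true},
    {"numeral": "VII",   "name": "MTase fold VII", "is_mtase": true},
    {"numeral": "VIII",  "name": "MTase fold VIII", "is_mtase": true},
    {"numeral": "IX",    "name": "MTase fold IX", "is_mtase": true},
    {"numeral": "X",     "name": "Non-MTase SAM-binding fold X", "is_mtase": false},
    {"numeral": "XI",    "name": "Non-MTase SAM-binding fold XI", "is_mtase": false},
    {"numeral": "XII",   "name": "Non-MTase SAM-binding fold XII", "is_mtase": false},
    {"numeral": "XIII",  "name": "Non-MTase SAM-binding fold XIII", "is_mtase": false},
    {"numeral": "XIV",   "name": "Non-MTase SAM-binding fold XIV", "is_mtase": false},
    {"numeral": "XV",    "name": "Non-MTase SAM-binding fold XV", "is_mtase": false},
    {"numeral": "XVI",   "name": "Non-MTase SAM-binding fold XVI", "is_mtase": false},
    {"numeral": "XVII",  "name": "Non-MTase SAM-binding fold XVII", "is_mtase": false},
    {"numeral": "XVIII", "name": "Non-MTase SAM-binding fold XVIII (helical bundle)", "is_mtase": false}
  ]
}
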