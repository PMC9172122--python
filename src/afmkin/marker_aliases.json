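{
  "version": "1.0",
  "description": "Mapping of common motion-capture lab labels to the model's canonical marker names. Side prefixes (R_, L_, R, L, RIGHT_, LEFT_) are stripped automatically by canonical_marker_name().",
  "aliases": {
    "TIB_TUB": "TT",
    "TIBTUB": "TT",
    "FIB_HEAD": "FH",
    "FIBHEAD": "FH",
    "ANT_SHANK": "ASHN",
    "LAT_SHANK": "LSHN",
    "LAT_MAL": "LM",
    "LATMAL": "LM",
    "ANK": "LM",
    "MED_MAL": "MM",
    "MEDMAL": "MM",
    "CAL_PROX": "CALP",
    "CALPROX": "CALP",
    "CAL_DIST": "CALD",
    "CALDIST": "CALD",
    "HEE": "CALD",
    "SUS_TAL": "ST",
    "SUSTAL": "ST",
    "PER_TUB": "PT",
    "PERTUB": "PT",
    "NAVI": "NAV",
    "TN": "NAV",
    "FMB": "BM1",
    "SMB": "BM2",
    "VMB": "BM5",
    "FMH": "HM1",
    "SMH": "HM2",
    "VMH": "HM5",
    "TOE": "HM2",
    "HALLUX": "HLX",
    "HLU": "HLX",
    "PM1": "HLX"
  }
}
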