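{
  "_comment": "PeptideCutter-style protease specificity rules (Keil). cleave_after: P1 residues; blocked_by_next: P1 -> P1' residues that veto the cut; exceptions: longer-context patterns, each {pattern, cut_index, action}. pattern is matched against the sequence, cut_index is the 0-based offset WITHIN the pattern of the residue after which the bond is (not) cut; action 'veto' suppresses a rule cut, 'allow' re-enables a cut vetoed by blocked_by_next.",
  "trypsin": {
    "cleave_after": ["K", "R"],
    "blocked_by_next": {"K": ["P"], "R": ["P"]},
    "exceptions": [
      {"pattern": "WKP", "cut_index": 1, "action": "allow"},
      {"pattern": "MRP", "cut_index": 1, "action": "allow"},
      {"pattern": "CKD", "cut_index": 1, "action": "veto"},
      {"pattern": "DKD", "cut_index": 1, "action": "veto"},
      {"pattern": "CKH", "cut_index": 1, "action": "veto"},
      {"pattern": "CKY", "cut_index": 1, "action": "veto"},
      {"pattern": "KKR", "cut_index": 1, "action": "veto"},
      {"pattern": "RRH", "cut_index": 1, "action": "veto"},
      {"pattern": "RRR", "cut_index": 1, "action": "veto"},
      {"pattern": "CRK", "cut_index": 1, "action": "veto"}
    ]
  },
  "chymotrypsin_high": {
    "cleave_after": ["F", "Y", "W"],
    "blocked_by_next": {"F": ["P"], "Y": ["P"], "W": ["M", "P"]},
    "exceptions": []
  },
  "chymotrypsin_low": {
    "cleave_after": ["F", "L", "M", "W", "Y"],
    "blocked_by_next": {"F": ["P"], "L": ["P"], "M": ["P", "Y"], "W": ["M", "P"], "Y": ["P"]},
    "exceptions": []
  }
}
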