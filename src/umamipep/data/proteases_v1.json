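{
  "version": "proteases-v1",
  "comment": "Twenty industrial proteases at P1/P1' resolution. Pepsin (pH 1.3) and pancreatic elastase follow published BIOPEP-UWM site lists verbatim; the remaining entries are field-standard PeptideCutter-style approximations of the corresponding enzyme specificities, reduced to single-position P1 with an optional P1' proline block. Each entry's notes record its provenance; multi-position preferences (P2, P1' beyond proline) are deliberately not modelled.",
  "rules": [
    {
      "name": "chymotrypsin A",
      "ec": "3.4.21.1",
      "side": "cterm",
      "p1": ["F", "Y", "W", "L", "M"],
      "blocked_p1prime": ["P"],
      "notes": "High-specificity aromatic P1 (F/Y/W) plus low-specificity L/M; Xaa-Pro bonds resistant. Approximation of the standard chymotrypsin rule."
    },
    {
      "name": "chymotrypsin C",
      "ec": "3.4.21.2",
      "side": "cterm",
      "p1": ["F", "Y", "W", "L", "M", "Q", "N"],
      "blocked_p1prime": ["P"],
      "notes": "Chymotrypsin-like with additional Gln/Asn P1 acceptance."
    },
    {
      "name": "metridin",
      "ec": "3.4.21.3",
      "side": "cterm",
      "p1": ["F", "Y", "W"],
      "blocked_p1prime": [],
      "notes": "Sea-anemone chymotrypsin-like protease; aromatic P1 approximation."
    },
    {
      "name": "pancreatic elastase",
      "ec": "3.4.21.36",
      "side": "cterm",
      "p1": ["A", "G", "V", "L", "I", "Y", "S", "T"],
      "blocked_p1prime": [],
      "notes": "P1 site list A,G,V,L,I,Y,S,T (C-terminus) as published for the BIOPEP-UWM entry."
    },
    {
      "name": "leukocyte elastase",
      "ec": "3.4.21.37",
      "side": "cterm",
      "p1": ["V", "A", "I", "L"],
      "blocked_p1prime": [],
      "notes": "Small-aliphatic P1 (Val preferred) approximation of neutrophil elastase."
    },
    {
      "name": "chymase",
      "ec": "3.4.21.39",
      "side": "cterm",
      "p1": ["F", "Y", "W"],
      "blocked_p1prime": ["P"],
      "notes": "Mast-cell chymase; chymotrypsin-like aromatic P1."
    },
    {
      "name": "trypsin",
      "ec": "3.4.21.4",
      "side": "cterm",
      "p1": ["K", "R"],
      "blocked_p1prime": ["P"],
      "notes": "Canonical Arg/Lys P1, Xaa-Pro resistant."
    },
    {
      "name": "subtilisin",
      "ec": "3.4.21.62",
      "side": "cterm",
      "p1": ["A", "F", "I", "L", "M", "V", "W", "Y"],
      "blocked_p1prime": [],
      "notes": "Broad specificity toward large uncharged P1 residues; approximation."
    },
    {
      "name": "proteinase K",
      "ec": "3.4.21.64",
      "side": "cterm",
      "p1": ["A", "E", "F", "I", "L", "T", "V", "W", "Y"],
      "blocked_p1prime": [],
      "notes": "Aliphatic/aromatic/hydrophobic P1 per the standard PeptideCutter rule."
    },
    {
      "name": "plasmin",
      "ec": "3.4.21.7",
      "side": "cterm",
      "p1": ["K", "R"],
      "blocked_p1prime": [],
      "notes": "Trypsin-like Arg/Lys P1; Lys preferred in vivo, not modelled."
    },
    {
      "name": "pancreatic elastase II",
      "ec": "3.4.21.71",
      "side": "cterm",
      "p1": ["F", "L", "M", "Y"],
      "blocked_p1prime": [],
      "notes": "Medium-sized hydrophobic P1 approximation."
    },
    {
      "name": "oligopeptidase B",
      "ec": "3.4.21.83",
      "side": "cterm",
      "p1": ["K", "R"],
      "blocked_p1prime": ["P"],
      "notes": "Basic P1, proline-blocked; exhaustive action assumed despite the enzyme's oligopeptide preference."
    },
    {
      "name": "proteinase P1 (lactocepin)",
      "ec": "3.4.21.96",
      "side": "cterm",
      "p1": ["A", "E", "F", "L", "M", "Q", "W", "Y"],
      "blocked_p1prime": [],
      "notes": "Lactococcal cell-envelope proteinase; broad hydrophobic/Gln/Glu P1 approximation."
    },
    {
      "name": "papain",
      "ec": "3.4.22.2",
      "side": "cterm",
      "p1": ["K", "R"],
      "blocked_p1prime": [],
      "notes": "P1 Arg/Lys; the enzyme's strong P2 hydrophobic preference is not modelled at P1/P1' resolution."
    },
    {
      "name": "ficin",
      "ec": "3.4.22.3",
      "side": "cterm",
      "p1": ["G", "K", "R"],
      "blocked_p1prime": [],
      "notes": "Papain-family; Gly/Lys/Arg P1 approximation."
    },
    {
      "name": "stem bromelain",
      "ec": "3.4.22.32",
      "side": "cterm",
      "p1": ["A", "G", "K", "Y"],
      "blocked_p1prime": [],
      "notes": "Papain-family with Ala/Gly/Lys/Tyr P1 approximation."
    },
    {
      "name": "calpain 2",
      "ec": "3.4.22.53",
      "side": "cterm",
      "p1": ["K", "M", "R", "Y"],
      "blocked_p1prime": [],
      "notes": "Calcium-activated neutral protease; Tyr/Met/Arg/Lys P1 approximation (true specificity is dominated by P2, not modelled)."
    },
    {
      "name": "pepsin (pH 1.3)",
      "ec": "3.4.23.1",
      "side": "cterm",
      "p1": ["F", "L", "G", "Y", "A", "E", "Q", "T"],
      "blocked_p1prime": [],
      "notes": "P1 site list F,L,G,Y,A,E,Q,T (C-terminus) as published for the BIOPEP-UWM pH 1.3 entry."
    },
    {
      "name": "thermolysin",
      "ec": "3.4.24.27",
      "side": "nterm",
      "p1": ["A", "F", "I", "L", "M", "V"],
      "blocked_p1prime": [],
      "notes": "Cleaves N-terminally to bulky hydrophobic residues (P1' specificity in classical nomenclature)."
    },
    {
      "name": "coccolysin",
      "ec": "3.4.24.30",
      "side": "nterm",
      "p1": ["F", "I", "L", "M", "V"],
      "blocked_p1prime": [],
      "notes": "Thermolysin-like gelatinase; hydrophobic N-terminal-side approximation."
    }
  ]
}
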