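{
  "version": "rna-wc-xia1998",
  "description": "Watson-Crick RNA nearest-neighbor parameters (Xia et al. 1998, 1 M NaCl). Stacks keyed 5'XY3'/3'WZ5'. dH kcal/mol, dS kcal/mol/K.",
  "stacks": {
    "AA/UU": {"dH": -6.82, "dS": -0.0190},
    "AU/AU": {"dH": -9.38, "dS": -0.0267},
    "UA/UA": {"dH": -7.69, "dS": -0.0205},
    "CU/AG": {"dH": -10.48, "dS": -0.0271},
    "CA/UG": {"dH": -10.44, "dS": -0.0269},
    "GU/AC": {"dH": -11.40, "dS": -0.0295},
    "GA/UC": {"dH": -12.44, "dS": -0.0325},
    "CG/CG": {"dH": -10.64, "dS": -0.0267},
    "GG/CC": {"dH": -13.39, "dS": -0.0327},
    "GC/GC": {"dH": -14.88, "dS": -0.0369}
  },
  "initiation": {"dH": 3.61, "dS": -0.0015},
  "terminal_au": {"dH": 3.72, "dS": 0.0105}
}
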