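{
  "version": "loops-turner2004-approx",
  "description": "Free-energy penalties (kcal/mol, treated as temperature-independent) for bulges and internal loops separating two helices in an intermolecular pairing state. Indexed by loop size: bulge by number of unpaired bases on the bulged strand, internal loop by total unpaired bases on both strands. Sizes beyond the table use a Jacobson-Stockmayer extrapolation dG(max) + 1.75*R*T37*ln(n/max).",
  "bulge": {"1": 3.8, "2": 2.8, "3": 3.2, "4": 3.6, "5": 4.0, "6": 4.4},
  "internal": {"2": 1.0, "3": 1.1, "4": 1.1, "5": 2.0, "6": 2.3}
}
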