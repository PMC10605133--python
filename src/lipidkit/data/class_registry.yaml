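# Lipid class registry: short code, display name, number of acyl/sphingoid
# chains carried by a fully resolved molecular species, and LIPID MAPS
# category. Extend or override via `nomenclature.load_registry`.
classes:
  - {code: CE,      full_name: Cholesteryl ester,                        chains: 1, category: sterol}
  - {code: Cer,     full_name: Ceramide,                                 chains: 2, category: sphingolipid}
  - {code: CL,      full_name: Cardiolipin,                              chains: 4, category: glycerophospholipid}
  - {code: DG,      full_name: Diacylglycerol,                           chains: 2, category: glycerolipid}
  - {code: PC-O,    full_name: Ether-linked phosphatidylcholine,         chains: 2, category: glycerophospholipid}
  - {code: PE-O,    full_name: Ether-linked phosphatidylethanolamine,    chains: 2, category: glycerophospholipid}
  - {code: PI-O,    full_name: Ether-linked phosphatidylinositol,        chains: 2, category: glycerophospholipid}
  - {code: HexCer,  full_name: Hexosylceramide,                          chains: 2, category: sphingolipid}
  - {code: LPC,     full_name: Lysophosphatidylcholine,                  chains: 1, category: glycerophospholipid}
  - {code: LPE,     full_name: Lysophosphatidylethanolamine,             chains: 1, category: glycerophospholipid}
  - {code: LPI,     full_name: Lysophosphatidylinositol,                 chains: 1, category: glycerophospholipid}
  - {code: PA,      full_name: Phosphatidic acid,                        chains: 2, category: glycerophospholipid}
  - {code: PC,      full_name: Phosphatidylcholine,                      chains: 2, category: glycerophospholipid}
  - {code: PE,      full_name: Phosphatidylethanolamine,                 chains: 2, category: glycerophospholipid}
  - {code: PG,      full_name: Phosphatidylglycerol,                     chains: 2, category: glycerophospholipid}
  - {code: PI,      full_name: Phosphatidylinositol,                     chains: 2, category: glycerophospholipid}
  - {code: PS,      full_name: Phosphatidylserine,                       chains: 2, category: glycerophospholipid}
  - {code: SHexCer, full_name: Sulfatide,                                chains: 2, category: sphingolipid}
  - {code: SM,      full_name: Sphingomyelin,                            chains: 2, category: sphingolipid}
  - {code: PSY,     full_name: Psychosine,                               chains: 1, category: sphingolipid}
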