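# Default internal-standard map for class-matched semi-quantification.
#
# The deuterated standard mix carries one labelled species per covered class,
# every component at the same stock concentration (100 ug/mL).  Classes with
# no labelled analogue in the mix borrow the closest chemistry:
#   HexCer / SHexCer -> ceramide standard (known over/under-estimation risk),
#   PC-O -> PC, PE-O -> PE, PI-O -> PI, LPI -> LPC, CL -> PG.
# Psychosine is quantified against its own deuterated standard (PSY-d5,
# 125 ng/mL spike).
#
# `dilution_factor` rescales every mix-derived spike concentration to the
# effective in-extract level; the default of 1.0 reports concentrations on
# the stock scale.  Ratio-based round trips are invariant to this factor.
dilution_factor: 1.0
standards:
  PC:      {species: "PC 15:0_18:1(d7) (IS)",       concentration: 100.0, unit: ug/mL}
  PC-O:    {species: "PC 15:0_18:1(d7) (IS)",       concentration: 100.0, unit: ug/mL}
  PE:      {species: "PE 15:0_18:1(d7) (IS)",       concentration: 100.0, unit: ug/mL}
  PE-O:    {species: "PE 15:0_18:1(d7) (IS)",       concentration: 100.0, unit: ug/mL}
  PS:      {species: "PS 15:0_18:1(d7) (IS)",       concentration: 100.0, unit: ug/mL}
  PG:      {species: "PG 15:0_18:1(d7) (IS)",       concentration: 100.0, unit: ug/mL}
  CL:      {species: "PG 15:0_18:1(d7) (IS)",       concentration: 100.0, unit: ug/mL}
  PI:      {species: "PI 15:0_18:1(d7) (IS)",       concentration: 100.0, unit: ug/mL}
  PI-O:    {species: "PI 15:0_18:1(d7) (IS)",       concentration: 100.0, unit: ug/mL}
  PA:      {species: "PA 15:0_18:1(d7) (IS)",       concentration: 100.0, unit: ug/mL}
  LPC:     {species: "LPC 18:1(d7) (IS)",           concentration: 100.0, unit: ug/mL}
  LPI:     {species: "LPC 18:1(d7) (IS)",           concentration: 100.0, unit: ug/mL}
  LPE:     {species: "LPE 18:1(d7) (IS)",           concentration: 100.0, unit: ug/mL}
  CE:      {species: "CE 18:1(d7) (IS)",            concentration: 100.0, unit: ug/mL}
  DG:      {species: "DG 15:0_18:1(d7) (IS)",       concentration: 100.0, unit: ug/mL}
  SM:      {species: "SM 18:1;O2/18:1(d9) (IS)",    concentration: 100.0, unit: ug/mL}
  Cer:     {species: "Cer 18:1;O2/15:0(d7) (IS)",   concentration: 100.0, unit: ug/mL}
  HexCer:  {species: "Cer 18:1;O2/15:0(d7) (IS)",   concentration: 100.0, unit: ug/mL}
  SHexCer: {species: "Cer 18:1;O2/15:0(d7) (IS)",   concentration: 100.0, unit: ug/mL}
  PSY:     {species: "PSY-d5 (IS)",                 concentration: 125.0, unit: ng/mL}
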