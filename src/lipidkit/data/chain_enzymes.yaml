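# Enzyme/gene annotation for fatty-acyl chain transformations, keyed by
# (edge type, substrate chain).  Chains are written "C:D".  Edges not listed
# fall back to the generic label for their type.
elongation:
  "16:0": {enzyme: elongase, genes: ELOVL1;ELOVL3;ELOVL6}
  "16:1": {enzyme: elongase, genes: ELOVL1;ELOVL3;ELOVL6}
  "18:0": {enzyme: elongase, genes: ELOVL1;ELOVL3;ELOVL6}
  "18:1": {enzyme: elongase, genes: ELOVL1;ELOVL3}
  "20:1": {enzyme: elongase, genes: ELOVL1;ELOVL3}
  "22:0": {enzyme: elongase, genes: ELOVL1;ELOVL3;ELOVL6}
desaturation:
  "16:0": {enzyme: stearoyl-CoA desaturase, genes: SCD1}
  "18:0": {enzyme: stearoyl-CoA desaturase, genes: SCD1}
  "18:1": {enzyme: delta-6 desaturase, genes: FADS2}
  "18:2": {enzyme: delta-6 desaturase, genes: FADS2}
  "20:3": {enzyme: delta-5 desaturase, genes: FADS1}
  "22:2": {enzyme: delta-5 desaturase, genes: FADS1}
defaults:
  elongation:     {enzyme: elongase,        genes: ELOVL}
  desaturation:   {enzyme: desaturase,      genes: FADS}
  beta_oxidation: {enzyme: beta-oxidation,  genes: ACOX;HADH}
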