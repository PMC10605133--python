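reactant,product,enzyme,genes
PA,PG,phosphatidate cytidylyltransferase,CDS
PA,PI,phosphatidate cytidylyltransferase,CDS
PI,PA,phospholipase D,PLD
PC,PA,phospholipase D,PLD
PC,PS,phosphatidylserine synthase 1,PSS1
PE,PS,phosphatidylserine synthase 2,PSS2
PA,PS,phosphatidate cytidylyltransferase + phosphatidylserine synthase,CDS;PSS
PC,PG,phospholipase D1/D4/D6,PLD1;PLD4;PLD6
CL,PG,mitoguardin / mitochondrial cardiolipin hydrolase,MIGA;PLD6
PC,LPC,phospholipase A,PLA
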