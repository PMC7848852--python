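code	category
PA	glycerophospholipid
LPA	glycerophospholipid
PC	glycerophospholipid
LPC	glycerophospholipid
PE	glycerophospholipid
LPE	glycerophospholipid
PS	glycerophospholipid
LPS	glycerophospholipid
PG	glycerophospholipid
LPG	glycerophospholipid
PI	glycerophospholipid
LPI	glycerophospholipid
CL	glycerophospholipid
MLCL	glycerophospholipid
O-PC	glycerophospholipid
O-LPC	glycerophospholipid
O-PE	glycerophospholipid
O-LPE	glycerophospholipid
MG	glycerolipid
DG	glycerolipid
TG	glycerolipid
O-MG	glycerolipid
O-DG	glycerolipid
O-TG	glycerolipid
SM	sphingolipid
dhSM	sphingolipid
Cer	sphingolipid
dhCer	sphingolipid
Cer1P	sphingolipid
dhCer1P	sphingolipid
Sph	sphingolipid
dhSph	sphingolipid
S1P	sphingolipid
dhS1P	sphingolipid
FA	fatty acyl
CoA	fatty acyl
CAR	fatty acyl
NAE	fatty acyl
WE	fatty acyl
CE	sterol
Chol	sterol
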