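name	smiles	scope
water	O	biochem
proton	[H+]	biochem
hydroxide	[OH-]	biochem
oxygen	O=O	biochem
hydrogen peroxide	OO	biochem
carbon dioxide	O=C=O	biochem
ammonia	N	biochem
ammonium	[NH4+]	biochem
phosphate	OP(=O)(O)O	biochem
hydrogenphosphate	OP(=O)(O)[O-]	biochem
diphosphate	OP(=O)(O)OP(=O)(O)O	biochem
NAD+	NC(=O)c1ccc[n+](c1)C1OC(COP(=O)(O)OP(=O)(O)OCC2OC(n3cnc4c(N)ncnc43)C(O)C2O)C(O)C1O	biochem
NADH	NC(=O)C1=CN(C=CC1)C1OC(COP(=O)(O)OP(=O)(O)OCC2OC(n3cnc4c(N)ncnc43)C(O)C2O)C(O)C1O	biochem
NADP+	NC(=O)c1ccc[n+](c1)C1OC(COP(=O)(O)OP(=O)(O)OCC2OC(n3cnc4c(N)ncnc43)C(OP(=O)(O)O)C2O)C(O)C1O	biochem
NADPH	NC(=O)C1=CN(C=CC1)C1OC(COP(=O)(O)OP(=O)(O)OCC2OC(n3cnc4c(N)ncnc43)C(OP(=O)(O)O)C2O)C(O)C1O	biochem
ATP	Nc1ncnc2n(cnc12)C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O	biochem
ADP	Nc1ncnc2n(cnc12)C1OC(COP(=O)(O)OP(=O)(O)O)C(O)C1O	biochem
AMP	Nc1ncnc2n(cnc12)C1OC(COP(=O)(O)O)C(O)C1O	biochem
FAD	Cc1cc2nc3c(=O)[nH]c(=O)n(C(CO)C(O)C(O)COP(=O)(O)OP(=O)(O)OCC4OC(n5cnc6c(N)ncnc65)C(O)C4O)c-3nc2cc1C	biochem
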