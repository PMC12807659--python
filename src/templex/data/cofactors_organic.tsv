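name	smiles	scope
water	O	organic
hydrochloric acid	Cl	organic
hydrobromic acid	Br	organic
sulfuric acid	OS(=O)(=O)O	organic
acetic acid	CC(=O)O	organic
methanol	CO	organic
ethanol	CCO	organic
triethylamine	CCN(CC)CC	organic
pyridine	c1ccncc1	organic
N,N-dimethylformamide	CN(C)C=O	organic
dimethyl sulfoxide	CS(C)=O	organic
tetrahydrofuran	C1CCOC1	organic
dichloromethane	ClCCl	organic
sodium cation	[Na+]	organic
potassium cation	[K+]	organic
chloride	[Cl-]	organic
hydroxide	[OH-]	organic
carbonate	[O-]C(=O)[O-]	organic
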