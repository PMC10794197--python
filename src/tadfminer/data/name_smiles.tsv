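# Built-in name → SMILES lookup table (test/default backend).
benzene	c1ccccc1
toluene	Cc1ccccc1
naphthalene	c1ccc2ccccc2c1
anthracene	c1ccc2cc3ccccc3cc2c1
pyrene	c1cc2ccc3cccc4ccc(c1)c2c34
carbazole	c1ccc2c(c1)[nH]c1ccccc12
biphenyl	c1ccc(-c2ccccc2)cc1
triphenylamine	c1ccc(N(c2ccccc2)c3ccccc3)cc1
phenol	Oc1ccccc1
aniline	Nc1ccccc1
pyridine	c1ccncc1
9-phenylcarbazole	c1ccc(-n2c3ccccc3c3ccccc32)cc1
4CzIPN	N#Cc1c(n2c3ccccc3c3ccccc32)c(n2c3ccccc3c3ccccc32)c(C#N)c(n2c3ccccc3c3ccccc32)c1n1c2ccccc2c2ccccc21
2CzPN	N#Cc1ccc(n2c3ccccc3c3ccccc32)c(n2c3ccccc3c3ccccc32)c1C#N
4,5-bis(carbazol-9-yl)-1,2-dicyanobenzene	N#Cc1ccc(n2c3ccccc3c3ccccc32)c(n2c3ccccc3c3ccccc32)c1C#N
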