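accession	category	description
CHOP780201	structural	alpha-helix propensity (Chou-Fasman)
CHOP780202	structural	beta-sheet propensity (Chou-Fasman)
CHOP780203	structural	beta-turn propensity (Chou-Fasman)
LEVM780101	structural	alpha-helix indices (Levitt)
LEVM780102	structural	beta-sheet indices (Levitt)
LEVM780103	structural	reverse-turn indices (Levitt)
ISOY800101	structural	alpha-helix normalized relative frequency
ISOY800102	structural	extended-structure normalized relative frequency
ISOY800103	structural	beta-turn normalized relative frequency
KANM800101	structural	average relative probability of helix
KANM800102	structural	average relative probability of beta-sheet
NAGK730101	structural	normalized frequency of alpha-helix
NAGK730102	structural	normalized frequency of beta-structure
NAGK730103	structural	normalized frequency of coil
PALJ810101	structural	normalized frequency of alpha-helix from LG
PALJ810102	structural	normalized frequency of alpha-helix from CF
ROBB760101	structural	information measure for alpha-helix
BURA740101	structural	normalized frequency of alpha-helix
GEIM800101	structural	alpha-helix indices
PRAM900102	structural	relative frequency in alpha-helix
PRAM900103	structural	relative frequency in beta-sheet
CHOC760103	structural	proportion of residues 95% buried
JANJ780101	structural	average accessible surface area
WERD780101	structural	propensity to be buried inside
KYTJ820101	physicochemical	hydropathy index (Kyte-Doolittle)
HOPT810101	physicochemical	hydrophilicity value (Hopp-Woods)
EISD840101	physicochemical	consensus normalized hydrophobicity
FAUJ830101	physicochemical	hydrophobic parameter pi
JOND750101	physicochemical	hydrophobicity
MANP780101	physicochemical	average surrounding hydrophobicity
PONP800101	physicochemical	surrounding hydrophobicity in folded form
ZIMJ680101	physicochemical	hydrophobicity
ZIMJ680102	physicochemical	bulkiness
ZIMJ680103	physicochemical	polarity
ZIMJ680104	physicochemical	isoelectric point
GRAR740102	physicochemical	polarity (Grantham)
GRAR740103	physicochemical	volume (Grantham)
KLEP840101	physicochemical	net charge
FAUJ880111	physicochemical	positive charge
FAUJ880112	physicochemical	negative charge
FAUJ880103	physicochemical	normalized van der Waals volume
BIGC670101	physicochemical	residue volume
CHOC750101	physicochemical	average volume of buried residue
GOLD730102	physicochemical	residue volume
KRIW790103	physicochemical	side chain volume
TSAJ990101	physicochemical	volume computed with Voronoi procedure
HARY940101	physicochemical	mean volume of residue buried
CHAM820101	physicochemical	polarizability parameter
RADA880108	physicochemical	mean polarity
WOLR810101	physicochemical	hydration potential
NOZY710101	physicochemical	transfer energy to organic solvent
LEVM760102	physicochemical	distance between C-alpha and side-chain centroid
LEVM760105	physicochemical	radius of gyration of side chain
DAWD720101	physicochemical	size
FASG760101	physicochemical	molecular weight
ARGP820101	physicochemical	hydrophobicity index (Argos)
PARJ860101	physicochemical	HPLC hydrophilicity
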