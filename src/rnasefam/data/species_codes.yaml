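# Two/three-letter species codes used in gene identifiers (<code>-<gene>),
# covering the 20 mammals of the bundled census. Unknown codes are accepted
# with a warning so synthetic or user-added taxa can flow through the pipeline.
Hs: Homo sapiens (human)
Pt: Pan troglodytes (chimpanzee)
Gg: Gorilla gorilla (gorilla)
Pp: Pongo pygmaeus (orangutan)
Nl: Nomascus leucogenys (gibbon)
Mmu: Macaca mulatta (rhesus macaque)
Cj: Callithrix jacchus (marmoset)
Mm: Mus musculus (mouse)
Rn: Rattus norvegicus (rat)
Hg: Heterocephalus glaber (naked mole rat)
Cp: Cavia porcellus (guinea pig)
Oc: Oryctolagus cuniculus (rabbit)
Bt: Bos taurus (cow)
Ec: Equus caballus (horse)
Cf: Canis familiaris (dog)
Am: Ailuropoda melanoleuca (giant panda)
Ml: Myotis lucifugus (little brown bat)
La: Loxodonta africana (African elephant)
Md: Monodelphis domestica (opossum)
Oa: Ornithorhynchus anatinus (platypus)
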