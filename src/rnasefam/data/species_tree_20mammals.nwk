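(((((((((((Hs:6.6,Pt:6.6)Hominini:1.7,Gg:8.3)Homininae:7.5,Pp:15.8)Hominidae:4.2,Nl:20)Hominoidea:9,Mmu:29)Catarrhini:14,Cj:43)Simiiformes:31,(((Mm:20.9,Rn:20.9)Muridae:49.1,(Hg:41,Cp:41)Hystricognathi:29)Rodentia:3,Oc:73)Glires:1)Euarchontoglires:18,(Ml:84,(Bt:82,(Ec:79,(Cf:39,Am:39)Caniformia:40)Zooamata:3)Fereuungulata:2)Laurasiatheria:8)Boreoeutheria:8,La:100)Eutheria:90,Md:190)Theria:30,Oa:220)Mammalia;
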