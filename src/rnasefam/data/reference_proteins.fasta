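>RNaseA_Bt_mature bovine pancreatic ribonuclease A, mature peptide; canonical-feature alignment profile (catalytic triad His/Lys/His, CKXXNTF motif, 8 cysteines); transcribed from the public database entry
KETAAAKFERQHMDSSTSAASSSNYCNQMMKSRNLTKDRCKPVNTFVHESLADVQAVCSQ
KNVACKNGQTNCYQSYSTMSITDCRETGSSKYPNCAYKTTQANKHIIVACEGNPYVPVHF
DASV
>RNase2_Hs_EDN_mature human eosinophil-derived neurotoxin (RNase2), mature peptide; curated transcription of the public database entry
KPPQFTWAQWFETQHINMTSQQCTNAMQVINNYQRRCKNQNTFLLTTFANVVNVCGNPNM
TCPSNKTRKNCHHSGSQVPLIHCNLTTPSPQNISNCRYAQTPANMFYIVACDNRDQRRDP
PQYPVVPVHLDRII
>RNase3_Hs_ECP_mature human eosinophil cationic protein (RNase3), mature peptide; curated transcription of the public database entry
RPPQFTRAQWFAIQHISLNPPRCTIAMRAINNYRWRCKNQNTFLRTTFANVVNVCGNQSI
RCPHNRTLNNCHRSRFRVPLLHCDLINPGAQNISNCRYADRPGRRFYVVACDNRDPRDSP
RYPVVPVHLDTTI
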