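# Secreted fibroblast (CAF) activators: TGF-beta superfamily (incl. activin
# subunits), PDGFs, EGF family, FGFs, sonic hedgehog.
TGFB1
TGFB2
TGFB3
INHBA
INHBB
INHA
BMP2
BMP4
BMP6
BMP7
GDF15
PDGFA
PDGFB
PDGFC
PDGFD
EGF
HBEGF
TGFA
AREG
EREG
BTC
EPGN
NRG1
FGF1
FGF2
FGF5
FGF7
FGF9
FGF10
SHH
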