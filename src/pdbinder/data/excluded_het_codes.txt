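# Hetero-group codes treated as crystallization buffer / cryoprotectant /
# solvent components rather than biologically relevant ligands.
# One three-letter code per line; lines starting with '#' are ignored.
# Edit freely: the file is read at run time.
ACT
ACY
BME
BOG
CIT
DMS
DOD
EDO
EPE
FMT
GOL
HOH
IMD
IOD
IPA
MES
MPD
MRD
NO3
P6G
PE4
PEG
PG4
PGE
PO4
SCN
SO4
TAR
TRS
UNX
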