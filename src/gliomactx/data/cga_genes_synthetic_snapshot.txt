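# Synthetic snapshot of well-known cancer/testis (cancer germline) antigen
# gene symbols, assembled by hand for offline use. Not a verbatim export of
# any database release; supply your own catalogue file for production use.
MAGEA1
MAGEA2
MAGEA3
MAGEA4
MAGEA6
MAGEA8
MAGEA9
MAGEA10
MAGEA11
MAGEA12
MAGEB1
MAGEB2
MAGEB3
MAGEB4
MAGEB6
MAGEC1
MAGEC2
MAGEC3
GAGE1
GAGE2A
GAGE2B
GAGE2C
GAGE4
GAGE5
GAGE6
GAGE7
PAGE1
PAGE2
PAGE3
PAGE4
PAGE5
XAGE1A
XAGE1B
XAGE2
XAGE3
XAGE5
CTAG1B
CTAG2
LAGE3
SSX1
SSX2
SSX3
SSX4
SSX5
SSX7
PRAME
BAGE
SAGE1
CSAG1
CSAG2
SPANXA1
SPANXB1
SPANXC
SPANXD
CT45A1
CT45A3
CT45A5
CT47A1
CT47B1
CTCFL
PIWIL1
PIWIL2
TDRD1
TDRD6
DDX43
DDX53
MORC1
TEX14
TEX15
TEX101
NXF2
TAF7L
TPTE
BRDT
PRSS50
ACRBP
CALR3
SYCP1
SPO11
HORMAD1
HORMAD2
CCDC62
LEMD1
OIP5
ADAM2
AKAP3
AKAP4
DKKL1
FMR1NB
GPAT2
IL13RA2
LUZP4
LY6K
ODF1
ODF2
PASD1
PBK
PLAC1
POTEA
RQCD1
SEMG1
SPA17
SPAG9
THEG
TSGA10
TSSK6
ZNF165
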