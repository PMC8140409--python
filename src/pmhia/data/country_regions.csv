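# Default three-region scheme for Europe, v1 (ISO-3166 alpha-2 codes).
# Western: Portugal, Spain, France, Italy, United Kingdom, Ireland.
# Central: Denmark, Finland, Norway, Sweden, Austria, Belgium, Germany,
#          Luxembourg, Netherlands, Switzerland.
# Eastern: Turkey, Belarus, Bulgaria, Czech Republic, Hungary, Poland,
#          Moldova, Romania, Russian Federation, Slovakia, Ukraine, Estonia,
#          Latvia, Lithuania, Albania, Bosnia and Herzegovina, Croatia,
#          Greece, Montenegro, North Macedonia, Serbia, Slovenia.
country,region
PT,Western
ES,Western
FR,Western
IT,Western
GB,Western
IE,Western
DK,Central
FI,Central
NO,Central
SE,Central
AT,Central
BE,Central
DE,Central
LU,Central
NL,Central
CH,Central
TR,Eastern
BY,Eastern
BG,Eastern
CZ,Eastern
HU,Eastern
PL,Eastern
MD,Eastern
RO,Eastern
RU,Eastern
SK,Eastern
UA,Eastern
EE,Eastern
LV,Eastern
LT,Eastern
AL,Eastern
BA,Eastern
HR,Eastern
GR,Eastern
ME,Eastern
MK,Eastern
RS,Eastern
SI,Eastern
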