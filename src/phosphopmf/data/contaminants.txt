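# Contaminant [M+H]+ monoisotopic masses for PMF peak erasure.
# label <tab-or-space> m/z
# Porcine trypsin autolysis products plus a curated stand-in set of
# common human keratin tryptic peptides.  Edit freely: this list is
# configuration, not code; the exact set used for any given instrument
# setup should be curated locally.
trypsin_108-115        842.5094
trypsin_209-216        906.5043
trypsin_98-107         1045.5637
trypsin_134-147        1469.7305
trypsin_58-72          1713.8084
trypsin_217-231        1736.8425
trypsin_116-133        1768.7990
trypsin_148-157        1111.5605
trypsin_58-77          2158.0307
trypsin_78-97          2211.1040
trypsin_209-228        2283.1802
keratin_K1_a           1179.6010
keratin_K1_b           1300.5302
keratin_K1_c           1475.7850
keratin_K1_d           2383.9520
keratin_K10_a          1165.5853
keratin_K10_b          1381.6771
keratin_K10_c          1707.7794
keratin_K2_a           1193.6166
keratin_K2_b           1320.6102
keratin_K9_a           1066.5118
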