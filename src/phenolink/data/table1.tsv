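#screen	phenotype_id
CellMorph	CMPO:0000052
CellMorph	CMPO:0000071
CellMorph	CMPO:0000077
CellMorph	CMPO:0000083
CellMorph	CMPO:0000105
CellMorph	CMPO:0000118
CellMorph	CMPO:0000128
CellMorph	CMPO:0000129
CellMorph	CMPO:0000154
CellMorph	CMPO:0000305
CellMorph	CMPO:0000340
MitoCheck	CMPO:0000030
MitoCheck	CMPO:0000140
MitoCheck	CMPO:0000156
MitoCheck	CMPO:0000157
MitoCheck	CMPO:0000202
MitoCheck	CMPO:0000213
MitoCheck	CMPO:0000216
MitoCheck	CMPO:0000236
MitoCheck	CMPO:0000237
MitoCheck	CMPO:0000241
MitoCheck	CMPO:0000307
MitoCheck	CMPO:0000326
MitoCheck	CMPO:0000344
MitoCheck	CMPO:0000345
MitoCheck	CMPO:0000348
EMBL_secretion	CMPO:0000246
EMBL_secretion	CMPO:0000318
EMBL_secretion	CMPO:0000319
EMBL_secretion	CMPO:0000346
GR00053	CMPO:0000182
GR00290	CMPO:0000361
GR00290	CMPO:0000362
Copenhagen_DNA_damage	CMPO:0000181
EMBL_chromosome_condensation	CMPO:0000328
EMBL_chromosome_condensation	CMPO:0000329
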