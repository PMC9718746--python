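symbol	source
TCL1A	lymphoid proto-oncogene; AKT co-activator overexpressed in T/B-cell malignancies
DNMT3A	recurrent clonal-hematopoiesis driver
TET2	recurrent clonal-hematopoiesis driver
ASXL1	recurrent clonal-hematopoiesis / MDS driver
JAK2	myeloproliferative-neoplasm driver
FLT3	AML driver
NPM1	AML driver
KIT	mastocytosis / AML driver
MYC	lymphoma driver
BCL2	follicular-lymphoma driver
CD79B	diffuse large B-cell lymphoma driver
NOTCH1	T-ALL / CLL driver
TP53	pan-cancer tumor suppressor, therapy-related myeloid neoplasms
RUNX1	familial platelet disorder with AML predisposition
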