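locus	repeat_unit	duplicated
DYS19	4	0
DYS389I	4	0
DYS389II	4	0
DYS390	4	0
DYS391	4	0
DYS392	3	0
DYS393	4	0
DYS437	4	0
DYS438	5	0
DYS439	4	0
DYS448	6	0
DYS456	4	0
DYS458	4	0
DYS635	4	0
Y-GATA-H4	4	0
DYS385	4	1
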