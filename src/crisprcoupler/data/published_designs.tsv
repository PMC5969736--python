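study	pair	distance_nt	element1_len	element2_len	pcr_cycles	note
Najm/Doench	sgRNA-1 to sgRNA-2	194	20	21	28 (single PCR)
Han/Bassik	sgRNA-1 to sgRNA-2	329	20	20	42 total (nested)	estimate from vector schematic
Shen/Mali	sgRNA-1 to sgRNA-2	329	20	20	28-34 total (nested)	estimate from vector schematic
Wong/Lu	sgRNA-1 to barcode-1	437	20	6	nested, cycles not provided	estimate from vector schematic
Wong/Lu	sgRNA-2 to barcode-2	94	20	6	nested, cycles not provided	estimate from vector schematic
Boettcher/McManus	sgRNA-1 to sgRNA-2	329	20	20	32 total (nested)	estimate from vector schematic
Current design	sgRNA-1 to barcode-1	82	20	6	22 (single PCR)
Current design	sgRNA-2 to barcode-2	82	21	6	22 (single PCR)
Current design	barcode-1 to barcode-2	17	6	6	22 (single PCR)
Current design	sgRNA-1 to sgRNA-2	193	20	21	22 (single PCR)
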