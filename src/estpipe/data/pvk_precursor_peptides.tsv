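name	sequence	amidated	previously_known
PVK-2	GLLAFPRV	1	1
PVK-3	DGAETPGAAASLWFGPRV	1	1
MT-2	TSSLFPHPRI	1	1
PVK-4	KGLVANARV	1	0
PVK-5	DSLWFGPRV	1	0
MT-3	SLRLRLPAAAWLAAGDVGNGKGDFTPRL	1	0
PVKDP	AGLGQDETRAGTK	0	0
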