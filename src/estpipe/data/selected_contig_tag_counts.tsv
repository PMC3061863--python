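contig_id	n_crowded	n_isolated	annotation
LC.228.C1.Contig298	9	0	Fasciclin(-like) precursor
LC.308.C2.Contig390	8	0	No annotation
LC.393.C1.Contig477	8	0	Similar to CG12163 (Cys-protease inhibitor)
LC.1955.C1.Contig2112	7	0	Similar to T-complex protein 1 subunit gamma
LC.4273.C1.Contig4391	7	0	No annotation
LC.446.C2.Contig534	5	0	Similar to 14-3-3 protein (leonardo protein)
LC.129.C1.Contig185	6	1	Slit homologue
LC.1849.C1.Contig2006	6	1	Signal peptidase complex subunit 2
LC.392.C1.Contig474	5	1	Probable cytochrome P450
LC.1602.C1.Contig1749	0	15	RNA helicase Ddx1
LC.587.C1.Contig691	0	11	G-protein gamma subunit
LC.1473.C1.Contig1619	0	7	No annotation
LC.312.C1.Contig394	0	7	Glutamine synthetase
LC.4308.C1.Contig4427	0	7	No annotation
LC.1603.C1.Contig1750	0	5	No annotation
LC.733.C2.Contig853	1	5	Similar to 7B2 precursor
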