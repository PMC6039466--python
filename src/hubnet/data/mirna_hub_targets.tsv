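hsa-mir-34a-5p	CTNNB1
hsa-mir-34a-5p	MAP3K7
hsa-mir-34a-5p	NDRG1
hsa-mir-423-3p	PABPC1
hsa-mir-423-3p	RXRA
hsa-mir-10a-5p	MAP3K7
hsa-mir-10a-5p	PABPC1
hsa-mir-34b-5p	CTNNB1
hsa-mir-34b-5p	MAP3K7
hsa-mir-182-5p	NDRG1
hsa-mir-182-5p	NR3C1
hsa-mir-19b-3p	NDRG1
hsa-mir-19b-3p	NR3C1
hsa-mir-155-5p	CTNNB1
hsa-mir-155-5p	NR3C1
hsa-let-7b-5p	NDRG1
hsa-let-7b-5p	PABPC1
hsa-mir-30a-5p	CTNNB1
hsa-mir-30a-5p	PABPC1
hsa-mir-320a	CTNNB1
hsa-mir-320a	RELA
hsa-mir-574-3p	RXRA
hsa-mir-488-5p	RXRA
hsa-mir-27a-3p	RXRA
hsa-mir-497-5p	MAP3K7
hsa-mir-16-5p	MAP3K7
hsa-mir-143-3p	MAP3K7
hsa-mir-15a-5p	MAP3K7
hsa-mir-646	MAP3K7
hsa-mir-107	MAP3K7
hsa-mir-195-5p	MAP3K7
hsa-mir-503-5p	MAP3K7
hsa-mir-424-5p	MAP3K7
hsa-mir-15b-5p	MAP3K7
hsa-mir-22-3p	NR3C1
hsa-mir-130b-3p	NR3C1
hsa-mir-17-5p	NR3C1
hsa-mir-106b-5p	NR3C1
hsa-mir-126-5p	NR3C1
hsa-mir-32-5p	NR3C1
hsa-mir-18a-5p	NR3C1
hsa-mir-137	NR3C1
hsa-mir-519d-3p	NR3C1
hsa-mir-106a-5p	NR3C1
hsa-mir-144-3p	NR3C1
hsa-mir-204-5p	NR3C1
hsa-mir-377-3p	NR3C1
hsa-mir-211-5p	NR3C1
hsa-mir-93-5p	NR3C1
hsa-mir-20a-5p	NR3C1
hsa-mir-20b-5p	NR3C1
hsa-mir-183-5p	NR3C1
hsa-mir-374a-5p	NR3C1
hsa-mir-369-3p	NR3C1
hsa-mir-200b-3p	PABPC1
hsa-mir-193b-3p	PABPC1
hsa-mir-429	PABPC1
hsa-mir-200c-3p	PABPC1
hsa-mir-125b-5p	PABPC1
hsa-mir-149-5p	PABPC1
hsa-mir-17-3p	PABPC1
hsa-mir-10b-5p	PABPC1
hsa-mir-1256	PABPC1
hsa-mir-34c-5p	PABPC1
hsa-mir-148a-3p	NDRG1
hsa-mir-24-3p	NDRG1
hsa-mir-19a-3p	NDRG1
hsa-mir-1290	NDRG1
hsa-mir-335-5p	NDRG1
hsa-mir-148b-3p	NDRG1
hsa-mir-152-3p	NDRG1
hsa-mir-342-3p	NDRG1
hsa-mir-7-5p	RELA
hsa-mir-30e-5p	RELA
hsa-mir-373-3p	RELA
hsa-mir-96-5p	RELA
hsa-mir-186-5p	RELA
hsa-mir-375	CTNNB1
hsa-mir-101-3p	CTNNB1
hsa-mir-221-3p	CTNNB1
hsa-mir-214-3p	CTNNB1
hsa-mir-331-3p	CTNNB1
hsa-mir-370-3p	CTNNB1
hsa-mir-200a-3p	CTNNB1
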