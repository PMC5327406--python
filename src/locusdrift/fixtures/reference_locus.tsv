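gene	scaffold	start	end	strand
LMAN1	ref_chr18	1	5000	+
ATP8B1	ref_chr18	10001	15000	+
NARS	ref_chr18	20001	25000	+
FECH	ref_chr18	30001	35000	+
ONECUT2	ref_chr18	40001	45000	+
ST8SIA3	ref_chr18	50001	55000	+
WDR7	ref_chr18	60001	65000	+
TXNL1	ref_chr18	70001	75000	+
TCF4	ref_chr18	80001	85000	+
CCD68	ref_chr18	90001	95000	+
CCD86	ref_chr18	100001	105000	+
RAB27B	ref_chr18	110001	115000	+
DYNAP	ref_chr18	120001	125000	+
C18OF54	ref_chr18	130001	135000	+
STARD6	ref_chr18	140001	145000	+
POLI	ref_chr18	150001	155000	+
MBD2	ref_chr18	160001	165000	+
DCC	ref_chr18	170001	175000	+
MEX3C	ref_chr18	180001	185000	+
SMAD4	ref_chr18	190001	195000	+
ELAC1	ref_chr18	200001	205000	+
ME2	ref_chr18	210001	215000	+
MRO	ref_chr18	220001	225000	+
MAPK4	ref_chr18	230001	235000	+
SKA1	ref_chr18	240001	245000	+
MYO5B	ref_chr18	250001	255000	+
ACAA2	ref_chr18	260001	265000	+
LIPG	ref_chr18	270001	275000	+
DYM	ref_chr18	280001	285000	+
SMAD7	ref_chr18	290001	295000	+
CTIF	ref_chr18	300001	305000	+
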