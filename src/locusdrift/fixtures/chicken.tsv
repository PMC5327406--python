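gene	scaffold	start	end	strand
LMAN1	chrZ	1	5000	+
ATP8B1	chrZ	10001	15000	+
NARS	chrZ	20001	25000	+
FECH	chrZ	30001	35000	+
ONECUT2	chrZ	40001	45000	+
ST8SIA3	chrZ	50001	55000	+
WDR7	chrZ	60001	65000	+
TXNL1	chrZ	70001	75000	+
TCF4	chrZ	80001	85000	+
CTIF	chrZ	90001	95000	-
SMAD7	chrZ	100001	105000	-
DYM	chrZ	110001	115000	-
LIPG	chrZ	120001	125000	-
ACAA2	chrZ	130001	135000	-
DYNAP	scaffold_A	1	5000	+
MBD2	scaffold_A	10001	15000	+
ME2	scaffold_B	1	5000	+
SMAD4	scaffold_C	1	5000	+
SKA1	scaffold_D	1	5000	+
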