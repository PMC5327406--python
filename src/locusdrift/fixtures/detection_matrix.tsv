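gene	ostrich	duck	chicken	quail	turkey	guineafowl	zebra_finch	ground_finch
LMAN1	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
ATP8B1	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
NARS	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
FECH	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
ONECUT2	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
ST8SIA3	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
WDR7	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
TXNL1	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
TCF4	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
CCD68	annotation	annotation	absent	absent	assembly	absent	absent	absent
CCD86	annotation	annotation	absent	absent	absent	absent	absent	absent
RAB27B	annotation	annotation	absent	absent	absent	absent	absent	absent
DYNAP	annotation	annotation	annotation	reads	annotation	reads	absent	reads
C18OF54	annotation	annotation	absent	absent	absent	absent	absent	absent
STARD6	annotation	annotation	absent	absent	absent	absent	absent	absent
POLI	annotation	annotation	absent	absent	absent	absent	absent	absent
MBD2	annotation	annotation	annotation	reads	annotation	reads	annotation	annotation
DCC	annotation	annotation	absent	absent	absent	absent	absent	absent
MEX3C	annotation	annotation	absent	absent	absent	absent	absent	absent
SMAD4	annotation	annotation	annotation	reads	annotation	reads	annotation	annotation
ELAC1	annotation	annotation	absent	absent	absent	absent	annotation	annotation
ME2	annotation	annotation	annotation	reads	annotation	reads	annotation	annotation
MRO	annotation	annotation	absent	absent	absent	absent	annotation	annotation
MAPK4	annotation	annotation	absent	absent	absent	absent	annotation	annotation
SKA1	annotation	annotation	annotation	reads	annotation	reads	annotation	annotation
MYO5B	annotation	annotation	absent	absent	absent	assembly	annotation	annotation
ACAA2	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
LIPG	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
DYM	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
SMAD7	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
CTIF	annotation	annotation	annotation	annotation	annotation	annotation	annotation	annotation
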