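order	common_name	assembly_top_hit	raw_reads_detected	transcriptome_detected
Galliformes	chicken	Neogenin	NO	NO
Galliformes	quail	Neogenin	NO	NO
Galliformes	turkey	Neogenin	NO	NO
Galliformes	guineafowl	Neogenin	NO	NO
Galliformes	brush_turkey	none_available	YES	none_available
Anseriformes	duck	DCC	YES	YES
Columbiformes	rock_pigeon	DCC	YES	YES
Cuculiformes	common_cuckoo	DCC	YES	NO
Apodiformes	annas_hummingbird	DCC	YES	none_available
Caprimulgiformes	chimney_swift	DCC	YES	NO
Opisthocomiformes	hoazin	DCC	YES	YES
Chradriiformes	killdeer	DCC	YES	NO
Sphenisciformes	emperor_penguin	DCC	YES	YES
Falconiformes	peregrine_falcon	DCC	YES	YES
Psittaciformes	budgerigar	DCC	YES	NO
Passeriformes	rifleman	Neogenin	YES	none_available
Passeriformes	hooded_crow	Neogenin	YES	YES
Passeriformes	ground_tit	Neogenin	YES	YES
Passeriformes	ground_finch	Neogenin	NO	none_available
Passeriformes	zebra_finch	Neogenin	NO	NO
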