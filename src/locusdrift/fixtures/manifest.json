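{
  "chicken.tsv": "a282b5a0f8999847ce09401fc17bed73447f6d42a373353d427814fd35aa0e59",
  "detection_matrix.tsv": "f3119ed958368dfe3d8efccc43fdc3cc3778491a23c19988f6a8f4f6bbc8fb99",
  "reference_locus.tsv": "ce4b297b91a5559debdafd8b1a24cc7d6faec871d027ca0f6f25173c7fc9143d",
  "table1.tsv": "d792edb16d3afc44ccc789d1cde05410fca5ad35b6d6dc3c3ac6c25c79838714",
  "turkey.tsv": "29c23b181e9eea207dbaceca18e87557c7e04c38cf1f14cb8c0f0423e575271a"
}
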