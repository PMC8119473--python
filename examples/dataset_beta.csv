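# fictional example entries illustrating the file format; these are NOT the
# published sources' real per-taxon assessments
taxon,label
Acer,Low allergenicity
Betula pendula,High allergenicity
Platanus acerifolia,Low allergenicity
Tilia cordata,Low allergenicity
Quercus,Low allergenicity
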