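# fictional example entries illustrating the file format; these are NOT the
# published sources' real per-taxon assessments
taxon,label
Acer,7
Acer platanoides,8
Betula pendula,9
Platanus acerifolia,7
Tilia cordata,3
Quercus,8
Ulmus,7
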