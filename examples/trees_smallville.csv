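id,species,x,y
1,Acer platanoides,120,340
2,Acer platanoides,135,355
3,Acer platanoides,150,360
4,Acer platanoides 'Crimson King',410,220
5,Acer saccharinum,430,240
6,Betula pendula,90,510
7,Betula pendula,105,525
8,Platanus x acerifolia,300,300
9,Platanus x acerifolia,315,312
10,Tilia cordata,520,480
11,Tilia cordata,535,495
12,Ginkgo biloba,610,150
13,Quercus rubra,700,700
14,Acer sp.,200,200
15,Ulmus americana,660,420
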