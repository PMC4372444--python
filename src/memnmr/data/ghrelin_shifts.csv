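residue_number,residue_name,atom,shift_ppm,uncertainty_ppm
1,GLY,CO,167.0,0.4
1,GLY,CA,40.9,0.2
2,SER,CO,172.1,0.2
2,SER,CA,55.6,0.5
2,SER,CB,62.5,0.6
3,SER,CA,53.6,0.1
3,SER,CB,63.3,0.2
3,SER,HA,4.5,0.3
4,PHE,CO,172.1,0.2
4,PHE,CA,55.8,1.2
4,PHE,CB,37.0,0.8
5,LEU,CO,174.8,0.4
5,LEU,CA,51.9,0.2
5,LEU,CB,40.7,0.5
6,SER,CO,169.3,0.5
6,SER,CA,54.2,0.5
6,SER,CB,61.2,0.6
7,PRO,CO,174.9,1.2
7,PRO,CA,61.2,0.5
7,PRO,CB,30.8,1.7
8,GLU,CO,174.1,0.2
8,GLU,CA,54.3,0.9
8,GLU,CB,25.8,0.9
10,GLN,CO,177.3,0.3
10,GLN,CA,55.4,0.4
10,GLN,CB,27.0,0.0
10,GLN,CG,34.4,0.9
10,GLN,HA,4.1,0.3
12,VAL,CO,174.1,0.2
12,VAL,CA,60.3,0.9
12,VAL,CB,30.0,0.3
13,GLN,CO,173.4,0.3
13,GLN,CA,53.5,0.2
13,GLN,CB,27.0,0.1
13,GLN,HA,4.3,0.3
13,GLN,HB,2.0,0.3
14,GLN,CO,173.5,0.3
14,GLN,CA,53.4,0.1
14,GLN,CB,27.0,0.1
14,GLN,CG,33.7,0.1
14,GLN,HA,4.3,0.3
14,GLN,HB,2.1,0.3
14,GLN,HG,2.4,0.3
18,SER,CO,171.8,0.2
18,SER,CA,55.8,0.1
18,SER,CB,61.3,0.2
18,SER,HA,4.4,0.3
18,SER,HB,3.9,0.3
21,PRO,CO,177.7,0.3
21,PRO,CA,59.0,0.1
21,PRO,CB,28.3,0.0
21,PRO,CG,24.8,0.1
21,PRO,CD,48.0,0.3
21,PRO,HA,4.7,0.3
21,PRO,HG,2.0,0.3
21,PRO,HD,3.8,0.3
22,PRO,CO,173.7,0.2
22,PRO,CA,60.4,0.2
22,PRO,CB,29.4,0.0
22,PRO,CG,24.8,0.3
22,PRO,CD,47.9,0.3
22,PRO,HA,4.4,0.3
23,ALA,CO,175.5,0.5
23,ALA,CA,50.5,0.6
23,ALA,CB,17.0,0.3
27,PRO,CO,173.3,0.0
27,PRO,CA,60.8,0.0
27,PRO,CB,29.4,0.1
27,PRO,CG,24.8,0.1
27,PRO,CD,48.1,0.3
27,PRO,HA,4.4,0.3
27,PRO,HB,2.0,0.3
27,PRO,HG,2.0,0.3
27,PRO,HD,3.8,0.3
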