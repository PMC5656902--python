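source_table,entry,catalyst_name,area_theta,rotation_barrier,ee_percent,mechanism,proximal_class_override
2,1,4-PhC6H4,50,2.01,-44,II,
2,2,"3,5-(CF3)2C6H4",62,2.02,-36,II,
2,3,Ph,70,2.05,-46,II,
2,4,2-naphthyl,49,2.13,-32,II,
2,5,"3,5-(tBu)2-4-OMeC6H3",35,2.51,-56,II,
2,6,1-naphthyl,62,13.43,35,I,
2,7,9-phenanthryl,48,14.25,75,I,
2,8,9-anthryl,61,26.53,89,I,
4,1,H,107,0.00,4,,
4,2,Ph,70,2.05,32,,
4,3,"3,5-(CF3)2C6H4",62,2.02,38,,
4,4,9-anthryl,61,28.31,66,,
4,5,"2,4,6-(iPr)3C6H3",51,28.40,91,,
4,6,4-PhC6H4,50,2.01,35,,
4,7,2-naphthyl,49,2.13,10,,
4,8,9-phenanthryl,48,14.45,22,,
4,9,"3,5-(tBu)2C6H4",41,2.65,72,,
4,10,SiPh3,29,1.35,25,,large
6,1,H,107,0.00,4,,
6,2,Ph,70,2.05,56,,
6,3,4-NO2C6H4,64,2.03,96,,
6,4,9-anthryl,61,28.31,25,,
6,5,SiPh3,29,1.35,9,,large
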