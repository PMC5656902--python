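source_table,reaction_name,mechanism_label,axis,nu_carbon_substituent,ee_small,ee_medium,ee_large,imine_cyclic,n_substituent_size,accessible_configs,nucleophile_kind,displaced_bulk
1,addition of diazophosphonates to N-Boc imines,I_E,area,,27,94,0,False,large,E,symmetrical,
1,addition of diazoacetimides to N-Boc imines,I_E,area,,30,80,,False,large,E,symmetrical,
1,Strecker reaction with N-Bn imines,I_E,area,,0,93,,False,large,E,symmetrical,
1,addition of alcohols to N-acyl imines,I_E,area,,52,94,,False,large,E,symmetrical,
1,addition of thiols to N-acyl imines,I_E,area,,11,91,,False,large,E,symmetrical,
1,peroxidation of N-acyl imines,I_E,area,,3,84,,False,large,E,symmetrical,
1,reduction of alkynyl esters,I_EZ,area,,-85,90,-22,False,large,E|Z,symmetrical,
1,reductive amination using benzothiazoline,I_Z,area,,90,97,6,False,large,E|Z,symmetrical,
1,reductive amination using Hantzsch ester,I_Z,area,,87,65,7,False,large,E|Z,symmetrical,
1,reduction of N-Ar imines,I_Z,area,,84,92,11,False,large,E|Z,symmetrical,
3,benzoxazine,I_Z,proximal,,36,81,94,True,large,Z,symmetrical,
3,indoles,I_Z,proximal,,42,72,97,True,large,Z,symmetrical,
3,quinoxalines,I_Z,proximal,,10,64,90,True,large,Z,symmetrical,
3,3-(trifluoromethyl)quinolones,I_Z,proximal,,-35,72,97,True,large,Z,symmetrical,
5,addition of indole to N-Ts imines,I_E,area,,73,93,0,False,large,E,displaced,small
5,addition of dihydroindole to N-Ts imines,I_E,area,,99,97,,False,large,E,displaced,small
5,Bignelli,I_II_E,area,,-96,80,,False,small,E,displaced,large
5,addition of indole to N-Boc imines,II_E,area,,2,92,,False,small,E,displaced,small
5,addition of enamides to N-acyl imines,II_E,area,,9,96,4,False,small,E,displaced,large
5,Povarov,II_E,area,,27,92,,False,small,E,displaced,small
7,addition of enamides to N-Boc imines,II_E,proximal,H,79,,91,False,small,E,displaced,small
7,Petasis Ferrier,II_E,proximal,H,,,99,False,small,E,displaced,small
7,addition of vinyl indoles to N-Boc imines,II_E,proximal,H,21,54,92,False,small,E,displaced,small
7,Bignelli,II_E,proximal,alkyl,99,64,1,False,small,E,displaced,large
7,Mannich of N-Ar imines,II_E,proximal,Ph,76,51,,False,small,E,displaced,large
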