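dtxsid,casrn,name,abbreviation,formula,smiles,rb2p,rb2p_measured,halflife_class
DTXSID20874028,914637-49-3,"2H,2H,3H,3H-Perfluorooctanoic acid",5:3 PFOA,C8H5F11O2,OC(=O)CCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID6027426,1691-99-2,2-Perfluorooctylsulfonyl-N-ethylaminoethyl alcohol,N-EtFOSE,C12H10F17NO3S,OCCN(CC)S(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID90382620,812-70-4,3-(Perfluoroheptyl)propanoic acid,7:3 FTCA,C10H5F15O2,OC(=O)CCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID00379268,356-02-5,3:3 Fluorotelomer carboxylic acid,3:3 FTCA,C6H5F7O2,OC(=O)CCC(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID30891564,757124-72-4,4:2 Fluorotelomer sulfonic acid,4:2 FTSA,C6H5F9O3S,OS(=O)(=O)CCC(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID90558000,57678-01-0,6:2 Fluorotelomer phosphate monoester,6:2 monoPAP,C8H6F13O4P,OP(=O)(O)OCCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID6067331,27619-97-2,6:2 Fluorotelomer sulfonic acid,6:2 FTSA,C8H5F13O3S,OS(=O)(=O)CCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID00192353,39108-34-4,8:2 Fluorotelomer sulfonic acid,8:2 FTS,C10H5F17O3S,OS(=O)(=O)CCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID8037708,3825-26-1,Ammonium perfluorooctanoate,PFOAA,C8F15O2.H4N,[NH4+].[O-]C(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID1032646,4151-50-2,N-Ethylperfluorooctanesulfonamide,NEtFOSA,C10H6F17NO2S,CCNS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID7027831,24448-09-7,N-Methyl-N-(2-hydroxyethyl)perfluorooctanesulfonamide,N-MeFOSE,C11H8F17NO3S,OCCN(C)S(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID1067629,31506-32-8,N-Methylperfluorooctanesulfonamide,N-MeFOSA,C9H4F17NO2S,CNS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID70880215,13252-13-6,Perfluoro-2-methyl-3-oxahexanoic acid,GenX,C6HF11O3,OC(=O)C(F)(C(F)(F)F)OC(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID5030030,375-73-5,Perfluorobutanesulfonic acid,PFBS,C4HF9O3S,OS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID4059916,375-22-4,Perfluorobutanoic acid,PFBA,C4HF7O2,OC(=O)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID3031860,335-76-2,Perfluorodecanoic acid,PFDA,C10HF19O2,OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID8059920,375-92-8,Perfluoroheptanesulfonic acid,PFHpS,C7HF15O3S,OS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID1037303,375-85-9,Perfluoroheptanoic acid,PFHpA,C7HF13O2,OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID50469320,41997-13-1,Perfluorohexanesulfonamide,FHxSA,C6H2F13NO2S,NS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID7040150,355-46-4,Perfluorohexanesulfonic acid,PFHxS,C6HF13O3S,OS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID3031862,307-24-4,Perfluorohexanoic acid,PFHxA,C6HF11O2,OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID8031863,375-95-1,Perfluorononanoic acid,PFNA,C9HF17O2,OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID3038939,754-91-6,Perfluorooctanesulfonamide,PFOSA,C8H2F17NO2S,NS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID3031864,1763-23-1,Perfluorooctanesulfonic acid,PFOS,C8HF17O3S,OS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID8031865,335-67-1,Perfluorooctanoic acid,PFOA,C8HF15O2,OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID6062599,2706-90-3,Perfluoropentanoic acid,PFPeA,C5HF9O2,OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,lt_1_week
DTXSID8059970,422-64-0,Perfluoropropanoic acid,PFPrA,C3HF5O2,OC(=O)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID3059921,376-06-7,Perfluorotetradecanoic acid,PFTeDA,C14HF27O2,OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID90868151,72629-94-8,Perfluorotridecanoic acid,PFTriDA,C13HF25O2,OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID8047553,2058-94-8,Perfluoroundecanoic acid,PFUnDA,C11HF21O2,OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
DTXSID3037707,29420-49-3,Potassium perfluorobutanesulfonate,KPFBS,C4F9O3S.K,[K+].[O-]S(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,,gt_2_months
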