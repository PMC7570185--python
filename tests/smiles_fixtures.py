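"""A fixture panel of drug-like SMILES for fingerprint oracle tests.

Well-known small-molecule drugs covering the functional-group space that
matters for E-state typing: aromatics and fused aromatics, nitro groups in
both charge-separated spellings, sulfones and sulfonamides, amides, ethers,
halogens, nitriles, azides, charged amines.
"""

DRUG_SMILES: dict[str, str] = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "ibuprofen": "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "naproxen": "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "theophylline": "Cn1c(=O)c2[nH]cnc2n(C)c1=O",
    "nicotine": "CN1CCCC1c1cccnc1",
    "metronidazole": "Cc1ncc([N+](=O)[O-])n1CCO",
    "chloramphenicol": "OC(c1ccc(cc1)[N+](=O)[O-])C(CO)NC(=O)C(Cl)Cl",
    "sulfamethoxazole": "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1",
    "furosemide": "NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl",
    "hydrochlorothiazide": "NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O",
    "celecoxib": "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "omeprazole": "COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1",
    "cimetidine": "Cc1nc[nH]c1CSCCNC(=NC)NC#N",
    "ranitidine": "CNC(=C[N+](=O)[O-])NCCSCc1ccc(CN(C)C)o1",
    "atenolol": "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
    "propranolol": "CC(C)NCC(O)COc1cccc2ccccc12",
    "warfarin": "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",
    "diazepam": "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",
    "fluoxetine": "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1",
    "sertraline": "CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21",
    "imatinib": "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1",
    "ciprofloxacin": "O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O",
    "penicillin_g": "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",
    "amoxicillin": "CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O",
    "morphine": "CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5",
    "quinine": "COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1",
    "allopurinol": "O=c1[nH]cnc2[nH]ncc12",
    "methotrexate": "CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc1",
    "captopril": "CC(CS)C(=O)N1CCCC1C(=O)O",
    "enalapril": "CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O",
    "simvastatin": "CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12",
    "metformin": "CN(C)C(=N)NC(=N)N",
    "glibenclamide": "COc1ccc(Cl)cc1C(=O)NCCc1ccc(S(=O)(=O)NC(=O)NC2CCCCC2)cc1",
    "tolbutamide": "CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1",
    "phenytoin": "O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1",
    "carbamazepine": "NC(=O)N1c2ccccc2C=Cc2ccccc21",
    "lamotrigine": "Nc1nnc(-c2cccc(Cl)c2Cl)c(N)n1",
    "zidovudine": "Cc1cn(C2CC(N=[N+]=[N-])C(CO)O2)c(=O)[nH]c1=O",
    "acyclovir": "Nc1nc2c(c(=O)[nH]1)ncn2COCCO",
    "levodopa": "NC(Cc1ccc(O)c(O)c1)C(=O)O",
    "tryptophan": "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "salbutamol": "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",
    "diclofenac": "O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl",
    "indomethacin": "COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1",
    "ketoprofen": "CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1",
    "piroxicam": "CN1S(=O)(=O)c2ccccc2C(O)=C1C(=O)Nc1ccccn1",
    "cetirizine": "OC(=O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1",
    "loratadine": "CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1",
    "dopamine": "NCCc1ccc(O)c(O)c1",
    "serotonin": "NCCc1c[nH]c2ccc(O)cc12",
    "histamine": "NCCc1c[nH]cn1",
    "epinephrine": "CNCC(O)c1ccc(O)c(O)c1",
    "folic_acid": "Nc1nc2ncc(CNc3ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc3)nc2c(=O)[nH]1",
    "valproate": "CCCC(CCC)C(=O)O",
    "gabapentin": "NCC1(CC(=O)O)CCCCC1",
    "pregabalin": "CC(C)CC(CN)CC(=O)O",
    "amlodipine": "CCOC(=O)C1=C(COCCN)NC(C)=C(C(=O)OC)C1c1ccccc1Cl",
    "lidocaine": "CCN(CC)CC(=O)Nc1c(C)cccc1C",
    "procaine": "CCN(CC)CCOC(=O)c1ccc(N)cc1",
    "chlorpromazine": "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",
    "haloperidol": "OC1(c2ccc(Cl)cc2)CCN(CCCC(=O)c2ccc(F)cc2)CC1",
}
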