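code,preferred_name,synonyms
APAP325,Acetaminophen 325 mg tablet,tylenol|paracetamol
APAP500,Acetaminophen 500 mg tablet,tylenol|paracetamol
APAPCOD,Acetaminophen-codeine 300-30 mg tablet,tylenol with codeine|tylenol #3
IBU200,Ibuprofen 200 mg tablet,advil|motrin
ASA81,Aspirin 81 mg tablet,baby aspirin|asa
METF500,Metformin 500 mg tablet,glucophage
METF1000,Metformin 1000 mg tablet,glucophage
GLIP5,Glipizide 5 mg tablet,glucotrol
INSGLAR,Insulin glargine 100 unit/mL,lantus
INSLISP,Insulin lispro 100 unit/mL,humalog
FURO40,Furosemide 40 mg tablet,lasix
LISIN10,Lisinopril 10 mg tablet,prinivil|zestril
METOP50,Metoprolol tartrate 50 mg tablet,lopressor
CARV625,Carvedilol 6.25 mg tablet,coreg
SPIRO25,Spironolactone 25 mg tablet,aldactone
DIGOX125,Digoxin 0.125 mg tablet,lanoxin
ATORV20,Atorvastatin 20 mg tablet,lipitor
SIMVA40,Simvastatin 40 mg tablet,zocor
OMEP20,Omeprazole 20 mg capsule,prilosec
LEVOT50,Levothyroxine 50 mcg tablet,synthroid
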