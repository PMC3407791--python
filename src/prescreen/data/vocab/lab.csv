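code,preferred_name,synonyms
HBA1C,Hemoglobin A1c,hga1c|a1c|glycated hemoglobin|glycosylated hemoglobin
GLU,Glucose serum,blood sugar|glucose
GLUF,Glucose fasting,fasting blood sugar
CREAT,Creatinine serum,creatinine
BUN,Blood urea nitrogen,urea nitrogen
NA,Sodium serum,sodium
K,Potassium serum,potassium
BNP,B-type natriuretic peptide,brain natriuretic peptide|bnp
TROP,Troponin I,troponin
TSH,Thyroid stimulating hormone,thyrotropin
LDL,LDL cholesterol,low density lipoprotein
HDL,HDL cholesterol,high density lipoprotein
TRIG,Triglycerides,
HGB,Hemoglobin,hgb
HCT,Hematocrit,hct
WBC,White blood cell count,leukocyte count
PLT,Platelet count,platelets
ALT,Alanine aminotransferase,sgpt
AST,Aspartate aminotransferase,sgot
EGFR,Estimated glomerular filtration rate,egfr
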