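code,preferred_name,synonyms
25000,Diabetes mellitus type II without complication,type 2 diabetes|t2dm|niddm
25002,Diabetes mellitus type II uncontrolled,type 2 diabetes uncontrolled|t2dm uncontrolled
25010,Diabetes with ketoacidosis type II,type 2 diabetes with ketoacidosis
25012,Diabetes with ketoacidosis type II uncontrolled,
4280,Congestive heart failure unspecified,chf|heart failure
4281,Left heart failure,heart failure left-sided
4289,Heart failure unspecified,heart failure nos
42830,Diastolic heart failure unspecified,diastolic heart failure
42831,Acute diastolic heart failure,
42832,Chronic diastolic heart failure,
42833,Acute on chronic diastolic heart failure,
40291,Hypertensive heart disease with heart failure,hypertensive heart failure
40401,Hypertensive heart and kidney disease with heart failure,
40491,Hypertensive heart and kidney disease with heart failure unspecified,
4019,Essential hypertension unspecified,hypertension|high blood pressure
2720,Pure hypercholesterolemia,high cholesterol
V220,Supervision of normal first pregnancy,pregnancy first
V221,Supervision of other normal pregnancy,pregnancy
V222,Pregnant state incidental,pregnancy incidental
4659,Acute upper respiratory infection,uri|common cold
7295,Pain in limb,limb pain
4140,Coronary atherosclerosis,cad|coronary artery disease
42731,Atrial fibrillation,afib
5859,Chronic kidney disease unspecified,ckd
49390,Asthma unspecified,asthma
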