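icd9,phecode,description,category,exclusion_lo,exclusion_hi,sex
278.00,278.1,Obesity,endocrine/metabolic,270,279.99,none
278.01,278.11,Morbid obesity,endocrine/metabolic,270,279.99,none
278.02,278.12,Overweight,endocrine/metabolic,270,279.99,none
250.00,250.2,Type 2 diabetes,endocrine/metabolic,249,250.99,none
250.02,250.2,Type 2 diabetes,endocrine/metabolic,249,250.99,none
250.40,250.2,Type 2 diabetes,endocrine/metabolic,249,250.99,none
327.23,327.3,Sleep apnea,neurological,327,327.99,none
780.53,327.3,Sleep apnea,neurological,327,327.99,none
780.57,327.3,Sleep apnea,neurological,327,327.99,none
610.1,610.1,Fibrocystic breast disease,genitourinary,610,612.99,female
610.2,610.1,Fibrocystic breast disease,genitourinary,610,612.99,female
571.8,571.5,Chronic nonalcoholic liver disease,digestive,571,571.99,none
571.5,571.5,Chronic nonalcoholic liver disease,digestive,571,571.99,none
041.10,041.1,Staphylococcus infections,infectious diseases,038,041.99,none
041.11,041.1,Staphylococcus infections,infectious diseases,038,041.99,none
041.00,041.2,Streptococcus infection,infectious diseases,038,041.99,none
041.01,041.2,Streptococcus infection,infectious diseases,038,041.99,none
481,480.1,Pneumococcal pneumonia,respiratory,480,488.99,none
038.2,038.1,Gram positive septicemia,infectious diseases,038,041.99,none
401.1,401.1,Essential hypertension,circulatory system,401,405.99,none
401.9,401.1,Essential hypertension,circulatory system,401,405.99,none
272.0,272.1,Hyperlipidemia,endocrine/metabolic,272,272.99,none
272.4,272.1,Hyperlipidemia,endocrine/metabolic,272,272.99,none
530.11,530.11,Gastroesophageal reflux disease,digestive,530,530.99,none
530.81,530.11,Gastroesophageal reflux disease,digestive,530,530.99,none
729.5,729.5,Pain in limb,musculoskeletal,729,729.99,none
780.79,780.7,Malaise and fatigue,symptoms,780.6,780.99,none
715.90,740.1,Osteoarthrosis,musculoskeletal,740,740.99,none
715.96,740.1,Osteoarthrosis,musculoskeletal,740,740.99,none
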