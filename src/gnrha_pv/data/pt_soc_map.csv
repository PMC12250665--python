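pt,soc
Ovarian hyperstimulation syndrome,Reproductive system and breast disorders
Amenorrhoea,Reproductive system and breast disorders
Vaginal haemorrhage,Reproductive system and breast disorders
Breast enlargement,Reproductive system and breast disorders
Delayed menarche,Reproductive system and breast disorders
Noninfective oophoritis,Reproductive system and breast disorders
Erectile dysfunction,Reproductive system and breast disorders
Pelvic pain,Reproductive system and breast disorders
Malignant neoplasm progression,"Neoplasms benign, malignant and unspecified (including cysts and polyps)"
Malignant spinal cord compression,"Neoplasms benign, malignant and unspecified (including cysts and polyps)"
Tumour flare,"Neoplasms benign, malignant and unspecified (including cysts and polyps)"
Prostate cancer metastatic,"Neoplasms benign, malignant and unspecified (including cysts and polyps)"
Breast cancer recurrent,"Neoplasms benign, malignant and unspecified (including cysts and polyps)"
Dysuria,Renal and urinary disorders
Haematuria,Renal and urinary disorders
Urinary tract toxicity,Renal and urinary disorders
Pollakiuria,Renal and urinary disorders
Renal impairment,Renal and urinary disorders
Bone pain,Musculoskeletal and connective tissue disorders
Premature fusion of epiphysis,Musculoskeletal and connective tissue disorders
Muscular weakness,Musculoskeletal and connective tissue disorders
Growth accelerated,Musculoskeletal and connective tissue disorders
Arthralgia,Musculoskeletal and connective tissue disorders
Osteonecrosis,Musculoskeletal and connective tissue disorders
Peripheral neuropathy,Nervous system disorders
Dementia Alzheimer's type,Nervous system disorders
Embolic stroke,Nervous system disorders
Headache,Nervous system disorders
Dizziness,Nervous system disorders
Paraesthesia,Nervous system disorders
Mood swings,Psychiatric disorders
Mood altered,Psychiatric disorders
Depression,Psychiatric disorders
Anxiety,Psychiatric disorders
Suicidal ideation,Psychiatric disorders
Rash,Skin and subcutaneous tissue disorders
Night sweats,Skin and subcutaneous tissue disorders
Hyperhidrosis,Skin and subcutaneous tissue disorders
Hair growth abnormal,Skin and subcutaneous tissue disorders
Alopecia,Skin and subcutaneous tissue disorders
Pruritus,Skin and subcutaneous tissue disorders
Nausea,Gastrointestinal disorders
Vomiting,Gastrointestinal disorders
Abdominal pain,Gastrointestinal disorders
Diarrhoea,Gastrointestinal disorders
Intestinal obstruction,Gastrointestinal disorders
Hot flush,Vascular disorders
Hypertension,Vascular disorders
Flushing,Vascular disorders
Deep vein thrombosis,Vascular disorders
Haemorrhage,Vascular disorders
Injection site pain,General disorders and administration site conditions
Fatigue,General disorders and administration site conditions
Pyrexia,General disorders and administration site conditions
Asthenia,General disorders and administration site conditions
Blood testosterone decreased,Investigations
Weight increased,Investigations
Blood pressure increased,Investigations
Fall,"Injury, poisoning and procedural complications"
Overdose,"Injury, poisoning and procedural complications"
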