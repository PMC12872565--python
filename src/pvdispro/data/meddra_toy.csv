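pt,soc
anaemia,Blood and lymphatic system disorders
thrombocytopenia,Blood and lymphatic system disorders
palpitations,Cardiac disorders
atrial fibrillation,Cardiac disorders
atrial septal defect,"Congenital, familial, and genetic disorders"
tinnitus,Ear and labyrinth disorders
vertigo,Ear and labyrinth disorders
hypothyroidism,Endocrine disorders
vision blurred,Eye disorders
visual impairment,Eye disorders
nausea,Gastrointestinal disorders
diarrhoea,Gastrointestinal disorders
abdominal pain,Gastrointestinal disorders
vomiting,Gastrointestinal disorders
fatigue,General disorders
asthenia,General disorders
malaise,General disorders
hepatitis,Hepatobiliary disorders
jaundice,Hepatobiliary disorders
hepatic steatosis,Hepatobiliary disorders
hypersensitivity,Immune system disorders
drug hypersensitivity,Immune system disorders
nasopharyngitis,Infections and infestations
urinary tract infection,Infections and infestations
fall,"Injury, poisoning, and procedural complications"
contusion,"Injury, poisoning, and procedural complications"
blood creatine phosphokinase increased,Investigations
alanine aminotransferase increased,Investigations
weight decreased,Investigations
gout,Metabolism and nutrition disorders
decreased appetite,Metabolism and nutrition disorders
hyperuricaemia,Metabolism and nutrition disorders
myalgia,Musculoskeletal and connective tissue disorders
rhabdomyolysis,Musculoskeletal and connective tissue disorders
muscle spasms,Musculoskeletal and connective tissue disorders
muscular weakness,Musculoskeletal and connective tissue disorders
myopathy,Musculoskeletal and connective tissue disorders
musculoskeletal stiffness,Musculoskeletal and connective tissue disorders
muscle disorder,Musculoskeletal and connective tissue disorders
muscle discomfort,Musculoskeletal and connective tissue disorders
musculoskeletal pain,Musculoskeletal and connective tissue disorders
musculoskeletal discomfort,Musculoskeletal and connective tissue disorders
myositis,Musculoskeletal and connective tissue disorders
necrotising myositis,Musculoskeletal and connective tissue disorders
arthralgia,Musculoskeletal and connective tissue disorders
pain in extremity,Musculoskeletal and connective tissue disorders
back pain,Musculoskeletal and connective tissue disorders
headache,Nervous system disorders
dizziness,Nervous system disorders
paraesthesia,Nervous system disorders
insomnia,Psychiatric disorders
anxiety,Psychiatric disorders
acute kidney injury,Renal and urinary disorders
renal impairment,Renal and urinary disorders
dyspnoea,"Respiratory, thoracic, and mediastinal disorders"
cough,"Respiratory, thoracic, and mediastinal disorders"
rash,Skin and subcutaneous tissue disorders
pruritus,Skin and subcutaneous tissue disorders
alopecia,Skin and subcutaneous tissue disorders
hypertension,Vascular disorders
flushing,Vascular disorders
hypotension,Vascular disorders
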