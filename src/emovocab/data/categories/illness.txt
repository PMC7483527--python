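# emovocab demo category: physical illness and health-complaint words
# (synthetic stand-in, authored for this package).
sick
sickness
ill
illness
flu
fever
clinic
doctor
doctors
hospital
pill
pills
medicine
medication
headache
migraine
pain
painful
ache
aches
aching
cough
coughing
symptom
symptoms
disease
infection
injury
injured
nurse
virus
nausea
dizzy
allergy
allergies
surgery
wound
bruise
rash
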