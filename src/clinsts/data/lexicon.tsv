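abdominal pain	C0000737
chest pain	C0008031
shortness of breath	C0013404
nausea	C0027497
vomiting	C0042963
fever	C0015967
headache	C0018681
dizziness	C0012833
cough	C0010200
sore throat	C0242429
fatigue	C0015672
rash	C0037284
swelling	C0038999
back pain	C0004604
otalgia	C0013456
stridor	C0038450
wheezing	C0043144
palpitations	C0030252
constipation	C0009806
diarrhea	C0011991
metformin	C0025598
ibuprofen	C0020740
insulin	C0021641
aspirin	C0004057
lisinopril	C0065374
amoxicillin	C0002645
acetaminophen	C0000970
hydrocortisone cream	C0063032
albuterol	C0001927
hypertension	C0020538
diabetes	C0011849
asthma	C0004096
pneumonia	C0032285
biopsy	C0005558
physical therapy	C0949766
home exercise program	C3714509
follow up	C0589120
blood pressure	C0005823
heart rate	C0018810
pain	C0030193
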