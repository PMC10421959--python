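term_id,display_name,domain,presence,severity,interference,frequency,amount
difficulty_swallowing,Difficulty swallowing,oral,0,1,0,0,0
mouth_throat_sores,Mouth/throat sores,oral,0,1,1,0,0
taste_changes,Taste changes,oral,0,1,0,0,0
decreased_appetite,Decreased appetite,gastrointestinal,0,1,1,0,0
nausea,Nausea,gastrointestinal,0,1,0,1,0
vomiting,Vomiting,gastrointestinal,0,1,0,1,0
heartburn,Heartburn,gastrointestinal,0,1,0,1,0
constipation,Constipation,gastrointestinal,0,1,0,0,0
diarrhea,Diarrhea,gastrointestinal,0,0,0,1,0
abdominal_pain,Abdominal pain,gastrointestinal,0,1,1,1,0
shortness_of_breath,Shortness of breath,respiratory,0,1,1,0,0
cough,Cough,respiratory,0,1,1,0,0
arm_leg_swelling,Arm or leg swelling,circulatory,0,1,1,1,0
rash,Rash,cutaneous,1,0,0,0,0
skin_dryness,Skin dryness,cutaneous,0,1,0,0,0
itching,Itching,cutaneous,0,1,0,0,0
hand_foot_syndrome,Hand-foot syndrome,cutaneous,0,1,0,0,0
numbness_tingling,Numbness & tingling,neurological,0,1,1,0,0
dizziness,Dizziness,neurological,0,1,1,0,0
visual_floaters,Visual floaters,visual_perceptual,1,0,0,0,0
ringing_in_ears,Ringing in ears,visual_perceptual,0,1,0,0,0
general_pain,General pain,pain,0,1,1,1,0
headache,Headache,pain,0,1,1,1,0
muscle_pain,Muscle pain,pain,0,1,1,1,0
joint_pain,Joint pain,pain,0,1,1,1,0
insomnia,Insomnia,sleep_wake,0,1,1,0,0
fatigue,"Fatigue, tiredness, or lack of energy",sleep_wake,0,1,1,0,0
anxious,Anxious,mood,0,1,1,1,0
sad,Sad or unhappy feelings,mood,0,1,1,1,0
urinary_incontinence,Urinary incontinence,genitourinary,0,0,1,1,0
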