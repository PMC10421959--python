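term_id,display_name,domain,presence,severity,interference,frequency,amount
dry_mouth,Dry mouth,oral,0,1,0,0,0
difficulty_swallowing,Difficulty swallowing,oral,0,1,0,0,0
mouth_throat_sores,Mouth/throat sores,oral,0,1,1,0,0
cheilosis,Cracking at the corners of the mouth (cheilosis/cheilitis),oral,0,1,0,0,0
voice_quality_changes,Voice quality changes,oral,1,0,0,0,0
hoarseness,Hoarseness,oral,0,1,0,0,0
taste_changes,Taste changes,oral,0,1,0,0,0
decreased_appetite,Decreased appetite,gastrointestinal,0,1,1,0,0
nausea,Nausea,gastrointestinal,0,1,0,1,0
vomiting,Vomiting,gastrointestinal,0,1,0,1,0
heartburn,Heartburn,gastrointestinal,0,1,0,1,0
gas,Gas,gastrointestinal,1,0,0,0,0
bloating,Bloating,gastrointestinal,0,1,0,1,0
hiccups,Hiccups,gastrointestinal,0,1,0,1,0
constipation,Constipation,gastrointestinal,0,1,0,0,0
diarrhea,Diarrhea,gastrointestinal,0,0,0,1,0
abdominal_pain,Abdominal pain,gastrointestinal,0,1,1,1,0
fecal_incontinence,Fecal incontinence,gastrointestinal,0,0,1,1,0
shortness_of_breath,Shortness of breath,respiratory,0,1,1,0,0
cough,Cough,respiratory,0,1,1,0,0
wheezing,Wheezing,respiratory,0,1,0,0,0
arm_leg_swelling,Arm or leg swelling,circulatory,0,1,1,1,0
heart_palpitations,Heart palpitations,circulatory,0,1,0,1,0
rash,Rash,cutaneous,1,0,0,0,0
skin_dryness,Skin dryness,cutaneous,0,1,0,0,0
acne,Acne,cutaneous,0,1,0,0,0
hair_loss,Hair loss,cutaneous,0,0,0,0,1
itching,Itching,cutaneous,0,1,0,0,0
hives,Hives,cutaneous,1,0,0,0,0
hand_foot_syndrome,Hand-foot syndrome,cutaneous,0,1,0,0,0
nail_loss,Nail loss,cutaneous,1,0,0,0,0
nail_ridging,Nail ridging,cutaneous,1,0,0,0,0
nail_discoloration,Nail discoloration,cutaneous,1,0,0,0,0
sensitivity_to_sunlight,Sensitivity to sunlight,cutaneous,1,0,0,0,0
bed_pressure_sores,Bed/pressure sores,cutaneous,1,0,0,0,0
radiation_skin_reaction,Radiation skin reaction,cutaneous,0,1,0,0,0
skin_darkening,Skin darkening,cutaneous,1,0,0,0,0
stretch_marks,Stretch marks,cutaneous,1,0,0,0,0
numbness_tingling,Numbness & tingling,neurological,0,1,1,0,0
dizziness,Dizziness,neurological,0,1,1,0,0
blurred_vision,Blurred vision,visual_perceptual,0,1,1,0,0
flashing_lights,Flashing lights,visual_perceptual,1,0,0,0,0
visual_floaters,Visual floaters,visual_perceptual,1,0,0,0,0
watery_eyes,Watery eyes,visual_perceptual,0,1,1,0,0
ringing_in_ears,Ringing in ears,visual_perceptual,0,1,0,0,0
concentration,Problems with concentration,attention_memory,0,1,1,0,0
memory,Problems with memory,attention_memory,0,1,1,0,0
general_pain,General pain,pain,0,1,1,1,0
headache,Headache,pain,0,1,1,1,0
muscle_pain,Muscle pain,pain,0,1,1,1,0
joint_pain,Joint pain,pain,0,1,1,1,0
insomnia,Insomnia,sleep_wake,0,1,1,0,0
fatigue,"Fatigue, tiredness, or lack of energy",sleep_wake,0,1,1,0,0
anxious,Anxious,mood,0,1,1,1,0
discouraged,Discouraged,mood,0,1,1,1,0
sad,Sad or unhappy feelings,mood,0,1,1,1,0
irregular_periods,Irregular periods/vaginal bleeding,genitourinary,1,0,0,0,0
missed_menstrual_period,Missed expected menstrual period,genitourinary,1,0,0,0,0
vaginal_discharge,Vaginal discharge,genitourinary,0,0,0,0,1
vaginal_dryness,Vaginal dryness,genitourinary,0,1,0,0,0
painful_urination,Painful urination,genitourinary,0,1,0,0,0
urinary_urgency,Urinary urgency,genitourinary,0,0,1,1,0
urinary_frequency,Urinary frequency,genitourinary,0,0,1,1,0
urine_color_change,Change in usual urine color,genitourinary,1,0,0,0,0
urinary_incontinence,Urinary incontinence,genitourinary,0,0,1,1,0
achieve_maintain_erection,Difficulty achieving and maintaining erection,sexual,0,1,0,0,0
ejaculation,Problems with ejaculation,sexual,0,0,0,1,0
decreased_libido,Decreased libido,sexual,0,1,0,0,0
delayed_orgasm,Delayed orgasm,sexual,1,0,0,0,0
unable_to_have_orgasm,Unable to have orgasm,sexual,1,0,0,0,0
pain_with_sexual_intercourse,Pain with sexual intercourse,sexual,0,1,0,0,0
breast_swelling_tenderness,Breast swelling and tenderness,miscellaneous,0,1,0,0,0
bruising,Bruising,miscellaneous,1,0,0,0,0
chills,Chills,miscellaneous,0,1,0,1,0
increased_sweating,Increased sweating,miscellaneous,0,1,0,1,0
decreased_sweating,Decreased sweating,miscellaneous,1,0,0,0,0
hot_flashes,Hot flashes,miscellaneous,0,1,0,1,0
nosebleed,Nosebleed,miscellaneous,0,1,0,1,0
injection_site_reaction,Pain and swelling at injection site,miscellaneous,1,0,0,0,0
body_odor,Body odor,miscellaneous,0,1,0,0,0
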