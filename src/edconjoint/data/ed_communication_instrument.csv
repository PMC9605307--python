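id,category,text
A1,Empathy,Clinicians care about me as a person
A2,Empathy,Clinicians are concerned about my comfort
A3,Empathy,Clinicians ask about my condition
A4,Empathy,Clinicians are courteous when they take my information
A5,Empathy,Clinicians monitor my condition
A6,Empathy,Clinicians are empathic
B1,Provide Information,Clinicians keep me informed
B2,Provide Information,Clinicians are clear
B3,Provide Information,Clinicians explain things to me
B4,Provide Information,Clinicians keep my family informed
B5,Provide Information,Clinicians keep me informed about delays
B6,Provide Information,Clinicians provide me with concise written discharge instructions
C1,Interpersonal skills,Clinicians carefully listen to me
C2,Interpersonal skills,Clinicians addresses my needs
C3,Interpersonal skills,Clinicians are discreet...respect my privacy
C4,Interpersonal skills,Clinicians show interest in me as a person
C5,Interpersonal skills,Clinicians pay attention to pain control
C6,Interpersonal skills,Clinicians respond patiently and promptly
D1,Comfort,Clinicians make efforts to minimize my wait time
D2,Comfort,Clinicians allow family and friends to sit with me
D3,Comfort,Clinicians move me through the process as quickly as possible
D4,Comfort,Clinicians move me quickly to the treatment area
D5,Comfort,Clinicians assure that I am comfortable in the waiting area
D6,Comfort,Clinicians see me quickly after my arrival
E1,"Encouraging questions, Avoiding Jargon and Role Clarity",Clinicians reframe from using medical jargon
E2,"Encouraging questions, Avoiding Jargon and Role Clarity",Clinicians maintain a calm and quiet setting
E3,"Encouraging questions, Avoiding Jargon and Role Clarity",Even from the start...I always know the role of the clinician in my room
E4,"Encouraging questions, Avoiding Jargon and Role Clarity",Clinicians treat me gently during exam
E5,"Encouraging questions, Avoiding Jargon and Role Clarity",Clinicians are experienced making me comfortable about procedures
E6,"Encouraging questions, Avoiding Jargon and Role Clarity",Clinicians encourage me to ask questions
F1,Bedside Manner,Clinicians are courteous to my family and friends
F2,Bedside Manner,Clinicians are attentive even in cases of long waiting times
F3,Bedside Manner,Clinicians address my physical AND mental states
F4,Bedside Manner,Clinicians guarantee privacy of my personal information
F5,Bedside Manner,Clinicians are compassionate
F6,Bedside Manner,Clinicians are there to help me
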