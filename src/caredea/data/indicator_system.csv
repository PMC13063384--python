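code,label,spo,mean,sd,cv,full_score_rate
1,Human resource input,S,4.88,0.34,0.07,87.5
1.1,Number of personnel,S,4.77,0.35,0.08,79.0
1.1.1,Number of licensed nurses,S,4.56,0.51,0.11,56.3
1.1.2,Number of frontline licensed nurses,S,4.25,0.86,0.20,43.8
1.1.3,Number of nursing interns,S,4.38,0.72,0.16,50.0
1.1.4,Number of nursing trainees,S,4.24,0.63,0.15,62.0
1.2,Nursing staff configuration structure,S,4.69,0.48,0.10,68.8
1.2.1,Proportion of nurses with different education levels,S,4.56,0.63,0.14,62.5
1.2.2,Proportion of nurses with different professional titles,S,4.56,0.73,0.16,68.8
1.2.3,Proportion of nurses with different years of work experience,S,4.50,0.52,0.11,50.0
1.2.4,Nurse-to-elderly ratio,S,4.50,0.82,0.18,68.8
1.2.5,Proportion of nurses on sick or maternity leave,S,4.31,0.79,0.18,50.0
2,Service input,S,4.76,0.24,0.08,87.5
2.1,Daily care hours required for the elderly,S,4.44,0.51,0.12,43.8
2.1.1,Care hours for elderly who are totally dependent,S,4.50,0.89,0.20,68.8
2.1.2,Care hours for elderly who are partially dependent,S,4.75,0.45,0.09,75.0
2.1.3,Care hours for elderly who are totally independent,S,4.56,0.63,0.14,62.5
2.2,Rehabilitation programs provided,S,4.69,0.48,0.10,68.8
2.2.1,Pulmonary rehabilitation exercise programs,S,4.50,0.63,0.14,56.3
2.2.2,Stroke rehabilitation exercise programs,S,4.50,0.52,0.11,50.0
2.2.3,Limb function rehabilitation exercise programs,S,4.31,0.95,0.22,56.3
3,Financial input,S,4.74,0.38,0.13,89.0
3.1,Annual salary income of nurses,S,4.53,0.37,0.11,77.0
3.2,Training funds for education science and research,S,4.63,0.50,0.11,62.5
3.2.1,Internal training funds,S,4.31,0.70,0.16,43.8
3.2.2,External training funds,S,4.19,0.54,0.13,25.0
4,Bed input,S,4.94,0.25,0.05,93.8
5,Nursing service output,P,4.94,0.25,0.05,93.8
5.1,Number of elderly admitted to the institution,P,4.50,0.52,0.11,50.0
5.2,Bed occupancy rate of the institution,P,4.53,0.45,0.13,62.5
5.3,Average length of stay for the elderly,P,4.72,0.23,0.09,89.5
6,Nursing safety output,O,4.72,0.24,0.06,86.0
6.1,Incidence of nursing adverse events,O,4.81,0.40,0.08,81.3
6.1.1,Nurse medication errors,O,4.37,0.49,0.16,56.3
6.1.2,Nurse failure to detect condition in time,O,4.69,0.48,0.10,68.8
6.1.3,Unplanned tube removal,O,3.88,1.02,0.26,37.5
6.1.4,Elderly wandering rate,O,4.63,0.50,0.11,62.5
6.1.5,Elderly fall rate,O,4.52,0.43,0.19,65.5
6.1.6,Elderly pressure ulcer rate,O,4.59,0.44,0.17,70.8
6.2,Incidence of nursing occupational exposure,O,4.23,0.37,0.12,79.0
7,Nursing quality output,P,4.79,0.30,0.17,85.5
7.1,Nurse assessment pass rate,P,4.69,0.48,0.10,68.8
7.1.1,Basic skill operation pass rate,P,4.75,0.58,0.12,81.3
7.1.2,Basic theory assessment pass rate,P,4.56,0.63,0.14,62.5
7.1.3,Elderly emergency plan assessment pass rate,P,4.63,0.62,0.13,68.8
7.2,Nursing quality inspection pass rate,P,4.46,0.37,0.15,56.3
7.2.1,100% pass rate of medicine expiry date,P,4.52,0.40,0.16,79.0
7.2.2,100% pass rate of medical supplies expiry date,P,4.63,0.50,0.11,62.5
7.2.3,100% pass rate of resuscitation equipment in good standby condition,P,4.81,0.40,0.08,81.3
7.2.4,Nursing documentation writing pass rate,P,4.56,0.73,0.16,68.8
7.2.5,Health guidance and education pass rate,P,4.69,0.48,0.10,68.8
7.3,Elderly treatment effectiveness rate,O,4.50,0.73,0.16,62.5
7.4,Elderly transfer effectiveness rate,O,3.88,0.81,0.21,25.0
8,Nursing teaching research and innovation output,O,4.38,0.24,0.05,89.5
8.1,Talent cultivation,O,4.81,0.54,0.11,87.5
8.1.1,Number of personnel with educational level upgrade,O,4.63,0.72,0.16,75.0
8.1.2,Number of personnel with professional title upgrade,O,4.50,0.63,0.14,56.3
8.1.3,Number of specialist nurses,O,3.56,1.21,0.34,31.3
8.1.4,Number of interns and trainees taught,O,4.43,0.36,0.12,75.0
8.2,Research output,O,4.81,0.40,0.08,81.3
8.2.1,Number of invention patents and new technologies,O,4.69,0.48,0.10,68.8
8.2.2,Number of articles published,O,4.63,0.62,0.13,68.8
8.2.3,Number of research projects obtained,O,4.56,0.63,0.14,62.5
9,Satisfaction,O,4.81,0.40,0.08,83.3
9.1,Elderly satisfaction,O,4.63,0.81,0.17,81.3
9.1.1,Satisfaction of the elderly themselves,O,4.56,0.51,0.11,56.3
9.1.2,Satisfaction of elderly family members,O,4.75,0.45,0.09,75.0
9.2,Nurse satisfaction,O,4.57,0.41,0.13,82.0
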