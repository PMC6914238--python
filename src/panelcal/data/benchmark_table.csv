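variable,level,group,source,unweighted_n,unweighted_pct,unweighted_reldiff_pct,weighted_pct,weighted_lo,weighted_hi,benchmark_pct,benchmark_lo,benchmark_hi,weighted_reldiff_pct,included
race_ethnicity,hispanic_latino,nonhealth,ACS,2271,7.61,-52.39,8.19,7.82,8.56,15.99,15.92,16.05,-48.78,1
race_ethnicity,white,nonhealth,ACS,24946,83.60,10.14,82.20,81.69,82.71,75.90,75.83,75.97,8.30,1
race_ethnicity,african_american,nonhealth,ACS,2838,9.51,-27.66,9.94,9.55,10.34,13.15,13.09,13.21,-24.35,1
race_ethnicity,asian,nonhealth,ACS,1164,3.90,-40.40,4.70,4.41,4.99,6.54,6.51,6.58,-28.16,1
race_ethnicity,american_indian_alaska_native,nonhealth,ACS,538,1.80,13.81,1.61,1.45,1.77,1.58,1.56,1.60,1.61,1
race_ethnicity,native_hawaiian_pacific_islander,nonhealth,ACS,108,0.36,-5.11,0.37,0.29,0.45,0.38,0.37,0.39,-3.31,1
race_ethnicity,other,nonhealth,ACS,1047,3.51,-29.90,3.88,3.62,4.15,5.01,4.97,5.04,-22.43,1
marital_status,married,nonhealth,ACS,15640,52.41,4.45,51.93,51.29,52.57,50.18,50.10,50.26,3.49,1
marital_status,widowed,nonhealth,ACS,1928,6.46,7.60,5.17,4.92,5.43,6.00,5.97,6.04,-13.82,1
marital_status,divorced,nonhealth,ACS,3969,13.30,16.08,11.50,11.12,11.89,11.46,11.41,11.51,0.40,1
marital_status,separated,nonhealth,ACS,576,1.93,,1.76,1.60,1.93,2.02,1.99,2.04,,0
marital_status,never_married,nonhealth,ACS,7728,25.90,-14.65,29.63,29.02,30.24,30.34,30.27,30.42,-2.35,1
education,less_than_high_school,nonhealth,ACS,834,2.79,-76.84,2.69,2.48,2.90,12.07,12.01,12.12,-77.73,1
education,high_school_or_ged,nonhealth,ACS,5846,19.59,-29.12,18.65,18.16,19.15,27.64,27.57,27.71,-32.50,1
education,some_college_or_associate,nonhealth,ACS,10003,33.52,8.69,32.98,32.38,33.58,30.84,30.77,30.91,6.95,1
education,bachelor_or_higher,nonhealth,ACS,13158,44.09,,45.68,45.04,46.31,29.45,29.38,29.52,,0
employed_last_week,yes,nonhealth,ACS,12005,40.23,-34.89,45.77,45.13,46.41,61.78,61.70,61.86,-25.92,1
employed_last_week,no,nonhealth,ACS,17836,59.77,,54.23,53.59,54.87,38.22,38.14,38.30,,0
private_insurance,yes,nonhealth,NHIS,19007,63.69,-2.25,64.81,64.20,65.42,65.16,64.21,66.11,-0.54,1
private_insurance,no,nonhealth,NHIS,10834,36.31,,35.19,34.58,35.80,34.84,33.89,35.79,,0
hospital_overnight_last_year,yes,health,NHIS,3609,12.09,43.13,9.65,9.30,10.01,8.45,8.17,8.72,14.26,1
hospital_overnight_last_year,no,health,NHIS,26232,87.91,,90.35,89.99,90.70,91.55,91.28,91.83,,0
alcohol_past_12m,yes,health,NHIS,15554,52.12,-3.88,52.10,51.46,52.74,54.23,53.15,55.31,-3.92,1
alcohol_past_12m,no,health,NHIS,14287,47.88,,47.90,47.26,48.54,45.77,44.69,46.85,,0
pain_reliever,lifetime_use,health,NSDUH,18287,61.28,-5.55,57.20,56.57,57.84,64.90,64.23,65.57,-11.83,1
pain_reliever,past_year_use,health,NSDUH,9607,32.19,-9.54,27.32,26.77,27.87,34.88,34.21,35.55,-23.24,1
pain_reliever,lifetime_nmu,health,NSDUH,3928,13.16,24.05,11.13,10.74,11.51,10.45,10.05,10.84,4.87,1
pain_reliever,past_year_nmu,health,NSDUH,2313,7.75,76.58,6.18,5.89,6.47,4.06,3.82,4.30,40.78,1
pain_reliever,past_month_nmu,health,NSDUH,1222,4.10,218.82,2.96,2.77,3.15,1.21,1.07,1.34,130.22,1
illicit_drug,lifetime_use,health,NSDUH,6230,20.88,-16.70,17.53,17.06,17.99,25.45,24.85,26.05,-30.07,1
illicit_drug,last_year_use,health,NSDUH,1756,5.88,54.63,4.74,4.49,5.00,4.08,3.85,4.31,24.61,1
illicit_drug,last_month_use,health,NSDUH,970,3.25,111.67,2.45,2.27,2.63,1.68,1.53,1.84,59.31,1
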