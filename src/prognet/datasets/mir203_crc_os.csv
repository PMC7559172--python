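study_id,first_author,year,country,ethnicity,specimen,males,females,n_patients,median_age,stage,assay,endogenous_control,endpoint,followup_months,hr,ci_lower,ci_upper
schetter_2008,Schetter et al,2008,USA,non-Asian,tissue,66,18,84,65,I-IV,RT-PCR,U6,OS,68,3.10,1.50,6.40
bovell_2013,Bovell et al,2013,USA,non-Asian,tissue,170,175,345,65,I-IV,RT-PCR,U6,OS,228,1.90,1.05,3.42
tao_2014,Tao et al,2014,China,Asian,tissue,47,43,90,70,I-IV,RT-PCR,U6,OS,27,1.38,0.77,2.48
deng_2016_c1,Deng et al (Cohort 1),2016,China,Asian,tissue,39,33,72,50,I-IV,RT-PCR,U6,OS,84,0.62,0.32,1.20
deng_2016_c2,Deng et al (Cohort 2),2016,China,Asian,serum,39,33,72,50,I-IV,RT-PCR,U6,OS,84,0.36,0.20,0.64
kingham_2017_c1,Kingham et al (Cohort 1),2017,USA,non-Asian,tissue,57,34,91,59,I-IV,RT-PCR,miR-331,OS,192,1.92,1.17,3.13
kingham_2017_c2,Kingham et al (Cohort 2),2017,USA,non-Asian,serum,31,15,46,56,I-IV,RT-PCR,miR-331,OS,60,1.98,1.14,3.42
takano_2017,Takano et al,2017,Japan,Asian,serum,147,93,240,,I-IV,RT-PCR,miR-16,OS,54,2.27,1.31,4.09
hur_2017_tissue,Hur et al (Cohort 1-tissue),2017,Japan,Asian,tissue,90,64,154,68,I-IV,RT-PCR,Cel-miR-39,OS,72,1.56,0.80,3.05
hur_2017_serum_a,Hur et al (Cohort 1-serum),2017,Japan,Asian,serum,107,79,186,68,I-IV,RT-PCR,Cel-miR-39,OS,72,2.14,1.09,4.21
hur_2017_serum_b,Hur et al (Cohort 1-serum),2017,Japan,Asian,serum,87,57,144,68,I-IV,RT-PCR,Cel-miR-39,OS,72,2.35,1.34,4.12
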