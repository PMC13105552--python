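name,age_low,age_high,base,ui_low,ui_high,distribution,units,source
cost_preparation,,,13572,6786,20358,triangular,usd,PCCSP
cost_initial_screen,,,3.26,1.63,4.89,triangular,usd,PCCSP
cost_colonoscopy,,,95.80,47.90,143.70,triangular,usd,PCCSP
cost_treatment_naa,,,706,353,1059,gamma,usd,PCCSP
cost_treatment_aa,,,1185,593,1778,gamma,usd,PCCSP
cost_treatment_crc1,,,6038,3019,9057,gamma,usd,PCCSP
cost_treatment_crc2,,,8821,4410,13231,gamma,usd,PCCSP
cost_treatment_crc3,,,9468,4734,14202,gamma,usd,PCCSP
cost_treatment_crc4,,,10265,5132,15397,gamma,usd,PCCSP
cost_diagnosis,,,86.43,43.22,129.65,gamma,usd,PCCSP
cost_followup,,,86.43,43.22,129.65,gamma,usd,PCCSP
participation_rate,,,0.5829,0.5052,0.5967,triangular,probability,PCCSP
screen_sensitivity_adenoma,,,0.5476,0.3530,0.6750,triangular,probability,literature
screen_sensitivity_crc,,,0.7778,0.4000,0.9510,triangular,probability,literature
screen_specificity,,,0.7170,0.5000,0.9000,triangular,probability,literature
colonoscopy_compliance,,,0.3892,0.2690,0.5290,triangular,probability,PCCSP
colonoscopy_sensitivity_naa,,,0.85,0.50,1.00,triangular,probability,literature
colonoscopy_sensitivity_aa,,,0.95,0.80,1.00,triangular,probability,literature
colonoscopy_sensitivity_crc,,,1.00,0.95,1.00,triangular,probability,literature
colonoscopy_specificity,,,0.95,0.95,1.00,triangular,probability,literature
p_normal_to_naa,40,49,0.0147,0.0073,0.0220,uniform,probability,calibration
p_normal_to_naa,50,54,0.0182,0.0091,0.0273,uniform,probability,calibration
p_normal_to_naa,55,59,0.0192,0.0096,0.0288,uniform,probability,calibration
p_normal_to_naa,60,64,0.0244,0.0122,0.0366,uniform,probability,calibration
p_normal_to_naa,65,69,0.0261,0.0131,0.0392,uniform,probability,calibration
p_normal_to_naa,70,74,0.0412,0.0206,0.0618,uniform,probability,calibration
p_normal_to_naa,75,79,0.0525,0.0263,0.0788,uniform,probability,calibration
p_normal_to_naa,80,82,0.0606,0.0303,0.0909,uniform,probability,calibration
p_naa_to_aa,40,49,0.0837,0.0418,0.1255,uniform,probability,calibration
p_naa_to_aa,50,54,0.1093,0.0547,0.1640,uniform,probability,calibration
p_naa_to_aa,55,59,0.1262,0.0631,0.1892,uniform,probability,calibration
p_naa_to_aa,60,64,0.1395,0.0698,0.2093,uniform,probability,calibration
p_naa_to_aa,65,69,0.1735,0.0868,0.2603,uniform,probability,calibration
p_naa_to_aa,70,74,0.2391,0.1196,0.3587,uniform,probability,calibration
p_naa_to_aa,75,79,0.2402,0.1201,0.3603,uniform,probability,calibration
p_naa_to_aa,80,82,0.2445,0.1222,0.3668,uniform,probability,calibration
p_aa_to_crc1,40,49,0.0158,0.0079,0.0237,uniform,probability,calibration
p_aa_to_crc1,50,54,0.0164,0.0082,0.0246,uniform,probability,calibration
p_aa_to_crc1,55,59,0.0171,0.0086,0.0257,uniform,probability,calibration
p_aa_to_crc1,60,64,0.0232,0.0116,0.0348,uniform,probability,calibration
p_aa_to_crc1,65,69,0.0260,0.0130,0.0390,uniform,probability,calibration
p_aa_to_crc1,70,74,0.0298,0.0149,0.0447,uniform,probability,calibration
p_aa_to_crc1,75,79,0.0302,0.0151,0.0454,uniform,probability,calibration
p_aa_to_crc1,80,82,0.0370,0.0185,0.0555,uniform,probability,calibration
p_crc1_to_crc2,,,0.30,0.10,0.50,beta,probability,literature
p_crc2_to_crc3,,,0.45,0.20,0.90,beta,probability,literature
p_crc3_to_crc4,,,0.50,0.30,1.00,beta,probability,literature
symptom_rate_naa,,,0.145,0.00,0.20,beta,probability,literature
symptom_rate_aa,,,0.145,0.00,0.20,beta,probability,literature
symptom_rate_crc1,,,0.07,0.00,0.30,beta,probability,literature
symptom_rate_crc2,,,0.25,0.20,0.50,beta,probability,literature
symptom_rate_crc3,,,0.55,0.50,0.70,beta,probability,literature
symptom_rate_crc4,,,0.85,0.70,1.00,beta,probability,literature
treatment_compliance_naa,,,0.60,0.50,0.70,beta,probability,literature
treatment_compliance_aa,,,0.80,0.70,0.90,beta,probability,literature
treatment_compliance_crc1,,,0.95,0.85,1.00,beta,probability,literature
treatment_compliance_crc2,,,0.95,0.85,1.00,beta,probability,literature
treatment_compliance_crc3,,,0.95,0.85,1.00,beta,probability,literature
treatment_compliance_crc4,,,0.95,0.85,1.00,beta,probability,literature
recurrence_naa,,,0.0663,0.0300,0.0900,uniform,probability,literature
recurrence_aa,,,0.1071,0.0500,0.1500,uniform,probability,literature
recurrence_crc1,,,0.0252,0.0200,0.0300,uniform,probability,literature
recurrence_crc2,,,0.0389,0.0300,0.0500,uniform,probability,literature
recurrence_crc3,,,0.0715,0.0600,0.0800,uniform,probability,literature
recurrence_crc4,,,0.1176,0.0800,0.1500,uniform,probability,assumption
utility_general,40,54,0.957,0.900,1.000,triangular,utility,literature
utility_general,55,59,0.955,0.900,1.000,triangular,utility,literature
utility_general,60,64,0.957,0.900,1.000,triangular,utility,literature
utility_general,65,82,0.943,0.900,1.000,triangular,utility,literature
utility_aa,,,0.83,0.80,0.90,beta,utility,literature
utility_crc1,,,0.74,0.70,0.80,beta,utility,literature
utility_crc2,,,0.74,0.60,0.80,beta,utility,literature
utility_crc3,,,0.67,0.50,0.80,beta,utility,literature
utility_crc4,,,0.25,0.10,0.60,beta,utility,literature
survival5_crc1,,,0.916,0.881,0.975,triangular,probability,literature
survival5_crc2,,,0.848,0.774,0.951,triangular,probability,literature
survival5_crc3,,,0.689,0.590,0.774,triangular,probability,literature
survival5_crc4,,,0.188,0.169,0.237,triangular,probability,literature
background_mortality,40,44,0.00109,0.00109,0.00109,fixed,probability,yearbook
background_mortality,45,49,0.00226,0.00226,0.00226,fixed,probability,yearbook
background_mortality,50,54,0.00349,0.00349,0.00349,fixed,probability,yearbook
background_mortality,55,59,0.00606,0.00606,0.00606,fixed,probability,yearbook
background_mortality,60,64,0.00875,0.00875,0.00875,fixed,probability,yearbook
background_mortality,65,69,0.01530,0.01530,0.01530,fixed,probability,yearbook
background_mortality,70,74,0.02443,0.02443,0.02443,fixed,probability,yearbook
background_mortality,75,79,0.04291,0.04291,0.04291,fixed,probability,yearbook
background_mortality,80,82,0.06802,0.06802,0.06802,fixed,probability,yearbook
discount_rate,,,0.03,0.00,0.05,uniform,rate,guideline
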