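metric,value
invitees,17780462
completers,10364955
screen_positives,1582606
colonoscopies,615912
detected_naa,114102
detected_aa,59954
detected_crc,5708
total_screening_cost_usd,95231764
crc_deaths_averted,19026
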