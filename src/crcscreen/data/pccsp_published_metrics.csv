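metric,lesion,value
detection_rate_pct,naa,21.18
detection_rate_pct,aa,11.55
detection_rate_pct,crc,1.10
yield_per_10k_participants,naa,43
yield_per_10k_participants,aa,24
yield_per_10k_participants,crc,3
yield_per_10k_participants,an,26
yield_per_10k_colonoscopies,naa,825
yield_per_10k_colonoscopies,aa,450
yield_per_10k_colonoscopies,crc,43
yield_per_10k_colonoscopies,an,493
colonoscopies_per_lesion,naa,6
colonoscopies_per_lesion,aa,11
colonoscopies_per_lesion,crc,108
colonoscopies_per_lesion,an,10
cost_per_lesion_usd,naa,835
cost_per_lesion_usd,aa,1588
cost_per_lesion_usd,crc,16684
cost_per_lesion_usd,an,1450
nns_initial_per_death_averted,crc,532
nns_clinical_per_death_averted,crc,64
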