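group_type,name,minimal_care_n,pct_minimal_care
region,East Asia and Pacific,12096,6
region,Europe and Central Asia,25424,5
region,Latin America and Caribbean,2618,1
region,Middle East and North Africa,74640,26
region,North America,0,0
region,South Asia,218238,50
region,Sub-Saharan Africa,102071,54
income,Lower-income countries (LIC),77626,65
income,Lower-middle-income countries (LMIC),357461,50
income,Upper-middle-income countries (UMIC),0,0
income,Higher-income countries (HIC),0,0
global,Global total,435087,
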