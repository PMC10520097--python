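region,era,rate
East Asia and Pacific,pre-2000,0.30
East Asia and Pacific,2000-2010,0.20
East Asia and Pacific,post-2010,0.10
Europe and Central Asia,pre-2000,0.15
Europe and Central Asia,2000-2010,0.08
Europe and Central Asia,post-2010,0.04
Latin America and Caribbean,pre-2000,0.25
Latin America and Caribbean,2000-2010,0.15
Latin America and Caribbean,post-2010,0.08
Middle East and North Africa,pre-2000,0.35
Middle East and North Africa,2000-2010,0.25
Middle East and North Africa,post-2010,0.15
North America,pre-2000,0.00
North America,2000-2010,0.00
North America,post-2010,0.00
South Asia,pre-2000,0.45
South Asia,2000-2010,0.35
South Asia,post-2010,0.25
Sub-Saharan Africa,pre-2000,0.60
Sub-Saharan Africa,2000-2010,0.60
Sub-Saharan Africa,post-2010,0.45
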