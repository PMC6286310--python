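kind,label,text,arm,position,decimals,expected,units
interval,RpL19_genomic_rescue,2R:24967017..24970096 Dmel_r6.08,,,2,3.08,kbp
interval,Xrp1_genomic_rescue,3R:18911505..18927381 Dmel_r6.08,,,2,15.88,kbp
interval,RpL19_IE-C5_deletion,2R:24968426..24969517 Dmel_r6.08,,,2,1.09,kbp
interval,Xrp1_mapped_interval,3R:18872668..18979166 Dmel_r6.08,,,1,106.5,kbp
change,Xrp1_frameshift_insertion,C > GATCCC,3R,18925226,,5,bp
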