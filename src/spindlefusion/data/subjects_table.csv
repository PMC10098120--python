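subject_id,group,psqi,first_cycle_min,first_cycle_spindles
DS1,DS,14,152.5,356
DS2,DS,17,96.5,121
DS3,DS,19,111.5,116
DS4,DS,16,75.5,65
DS5,DS,16,86,140
DS6,DS,18,61,77
DS7,DS,11,117,266
DS8,DS,13,101.5,114
DS9,DS,16,72,92
DS10,DS,14,82,130
DS11,DS,12,108.5,308
DS12,DS,18,81,124
DS13,DS,20,68.5,94
DS14,DS,16,65,101
DS15,DS,15,97,284
DS16,DS,20,150,162
DS17,DS,18,67,112
DS18,DS,17,107,179
DS19,DS,14,72.5,86
DS20,DS,16,111.5,190
NS1,NS,3,98.5,285
NS2,NS,2,76.5,187
NS3,NS,7,80.5,233
NS4,NS,9,115,200
NS5,NS,2,133.5,483
NS6,NS,5,72.5,171
NS7,NS,6,85.5,240
NS8,NS,8,126,297
NS9,NS,1,160,579
NS10,NS,9,108.5,257
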