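age_band,sex,draw_time,fasting,cutoff
<10,any,morning,False,65
<10,any,afternoon,False,57
>=10,male,morning,False,70
>=10,female,morning,False,66
>=10,male,afternoon,False,61
>=10,female,afternoon,False,59
>=10,male,morning,True,74
>=10,female,morning,True,70
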