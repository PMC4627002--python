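# n_lost=338	reference=never-exposed
label	cases	alive_noncases	deceased_other
never-exposed	14	414	37
0-2085.7 ppt-mo	47	826	99
>=2085.8 ppt-mo	14	112	36
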