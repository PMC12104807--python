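family	Cnidaria	Xenacoelomorpha	Protostomia	Chordata	Ambulacraria
anthozoa_I	1	1	0	0	0
chaopsin	1	0	0	1	1
xenopsin	1	?	1	0	0
c_opsin	0	0	1	1	1
r_opsin_canonical	0	1	1	1	1
r_opsin_noncanonical	0	0	1	1	1
go_opsin	0	0	1	1	1
neuropsin	0	0	1	1	1
rgr_retinochrome	0	1	1	1	1
bathyopsin	0	1	1	1	1
xeno_specific	0	1	0	0	0
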