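# Built-in single-value library (SVL) defaults: one conformation-independent
# (mean, sigma) per residue group and backbone parameter, in the Engh & Huber
# convention of per-class single ideal values. These are conventional
# round-number defaults for the group decomposition used here, editable by
# the user; lengths in Angstrom, angles in degrees. The three carbonyl angles
# of each group sum to 360 (planar sp2 carbon).
group	param	mean	sigma
General	N-CA	1.459	0.020
General	CA-C	1.525	0.026
General	C-O	1.229	0.019
General	CA-CB	1.532	0.020
General	C-N	1.336	0.023
General	C-N-CA	121.7	1.8
General	N-CA-C	111.0	2.8
General	N-CA-CB	110.6	1.8
General	CB-CA-C	110.6	2.0
General	CA-C-O	120.1	2.1
General	CA-C-N	117.2	2.2
General	O-C-N	122.7	1.6
Gly	N-CA	1.456	0.015
Gly	CA-C	1.514	0.016
Gly	C-O	1.232	0.016
Gly	C-N	1.326	0.018
Gly	C-N-CA	122.3	2.1
Gly	N-CA-C	113.1	2.5
Gly	CA-C-O	120.6	1.8
Gly	CA-C-N	116.2	2.0
Gly	O-C-N	123.2	1.7
Pro	N-CA	1.468	0.017
Pro	CA-C	1.524	0.020
Pro	C-O	1.228	0.020
Pro	CA-CB	1.531	0.020
Pro	C-N	1.338	0.019
Pro	C-N-CA	119.3	1.5
Pro	N-CA-C	112.1	2.6
Pro	N-CA-CB	103.0	1.1
Pro	CB-CA-C	111.7	2.1
Pro	CA-C-O	120.2	2.4
Pro	CA-C-N	117.1	2.8
Pro	O-C-N	122.7	1.6
IleVal	N-CA	1.459	0.020
IleVal	CA-C	1.525	0.026
IleVal	C-O	1.229	0.019
IleVal	CA-CB	1.540	0.027
IleVal	C-N	1.336	0.023
IleVal	C-N-CA	121.7	1.8
IleVal	N-CA-C	109.1	2.2
IleVal	N-CA-CB	110.8	2.3
IleVal	CB-CA-C	111.5	2.3
IleVal	CA-C-O	120.1	2.1
IleVal	CA-C-N	117.2	2.2
IleVal	O-C-N	122.7	1.6
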