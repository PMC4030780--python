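proband_id	hpo_terms	source
F1	HP:0002817;HP:0001999;HP:0000062;HP:0001627;HP:0002575;HP:0000104;HP:0000772;HP:0000925;HP:0002650;HP:0001363;HP:0000347;HP:0001762;HP:0010442;HP:0001159;HP:0003026	postmortem
F2	HP:0001631;HP:0001392;HP:0010442;HP:0000871;HP:0012443	pediatric
F3	HP:0012443;HP:0002119	ultrasound
F5	HP:0001660;HP:0011611;HP:0002021	postmortem
F6	HP:0001696;HP:0001629;HP:0012437	postmortem
F7	HP:0001627;HP:0002119	ultrasound
F8	HP:0000925;HP:0001762	ultrasound
F9	HP:0012443;HP:0001762	postmortem
F10	HP:0001989;HP:0002804	postmortem
F11	HP:0001627	ultrasound
F12	HP:0002119	ultrasound
F13	HP:0000003;HP:0000772;HP:0000925;HP:0012443;HP:0001762	postmortem
F14	HP:0002119;HP:0001274	ultrasound
F15	HP:0001629;HP:0000347	ultrasound
F16	HP:0012443;HP:0002119	ultrasound
F17	HP:0000104	ultrasound
F18	HP:0001627;HP:0000925	postmortem
F19	HP:0001631;HP:0002575;HP:0000202	postmortem
F20	HP:0010880;HP:0005180;HP:0001762	ultrasound
F21	HP:0002119;HP:0001999	ultrasound
F22	HP:0001627	ultrasound
F23	HP:0002652;HP:0003026;HP:0000774	ultrasound
F25	HP:0001274;HP:0000252	pediatric
F26	HP:0001629	ultrasound
F27	HP:0002119;HP:0001274	ultrasound
F28	HP:0001627;HP:0001392	pediatric
F29	HP:0000925;HP:0002650	ultrasound
F31	HP:0001762	ultrasound
F32	HP:0002119	ultrasound
F33	HP:0001274;HP:0012443	postmortem
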