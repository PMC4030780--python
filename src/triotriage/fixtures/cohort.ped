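FAM1	P1	0	0	1	1	.
FAM1	M1	0	0	2	1	.
FAM1	F1	P1	M1	1	2	.
FAM2	P2	0	0	1	1	.
FAM2	M2	0	0	2	1	.
FAM2	F2	P2	M2	2	2	.
FAM3	P3	0	0	1	1	.
FAM3	M3	0	0	2	1	.
FAM3	F3	P3	M3	1	2	MZ:F16
FAM3	F16	P3	M3	1	2	MZ:F3
FAM5	P5	0	0	1	1	.
FAM5	M5	0	0	2	1	.
FAM5	F5	P5	M5	1	2	.
FAM6	P6	0	0	1	1	.
FAM6	M6	0	0	2	1	.
FAM6	F6	P6	M6	2	2	.
FAM7	P7	0	0	1	1	.
FAM7	M7	0	0	2	1	.
FAM7	F7	P7	M7	2	2	.
FAM8	P8	0	0	1	1	.
FAM8	M8	0	0	2	1	.
FAM8	F8	P8	M8	1	2	.
FAM9	P9	0	0	1	1	.
FAM9	M9	0	0	2	1	.
FAM9	F9	P9	M9	1	2	.
FAM10	P10	0	0	1	1	.
FAM10	M10	0	0	2	1	.
FAM10	F10	P10	M10	2	2	.
FAM11	P11	0	0	1	1	.
FAM11	M11	0	0	2	1	.
FAM11	F11	P11	M11	1	2	.
FAM12	P12	0	0	1	1	.
FAM12	M12	0	0	2	1	.
FAM12	F12	P12	M12	2	2	.
FAM13	P13	0	0	1	1	.
FAM13	M13	0	0	2	1	.
FAM13	F13	P13	M13	1	2	.
FAM14	P14	0	0	1	1	.
FAM14	M14	0	0	2	1	.
FAM14	F14	P14	M14	2	2	.
FAM15	P15	0	0	1	1	.
FAM15	M15	0	0	2	1	.
FAM15	F15	P15	M15	2	2	.
FAM17	P17	0	0	1	1	.
FAM17	M17	0	0	2	1	.
FAM17	F17	P17	M17	2	2	.
FAM18	P18	0	0	1	1	.
FAM18	M18	0	0	2	1	.
FAM18	F18	P18	M18	1	2	.
FAM19	P19	0	0	1	1	.
FAM19	M19	0	0	2	1	.
FAM19	F19	P19	M19	1	2	.
FAM20	P20	0	0	1	1	.
FAM20	M20	0	0	2	1	.
FAM20	F20	P20	M20	1	2	.
FAM21	P21	0	0	1	1	.
FAM21	M21	0	0	2	1	.
FAM21	F21	P21	M21	1	2	.
FAM22	P22	0	0	1	1	.
FAM22	M22	0	0	2	1	.
FAM22	F22	P22	M22	1	2	.
FAM23	P23	0	0	1	1	.
FAM23	M23	0	0	2	1	.
FAM23	F23	P23	M23	1	2	.
FAM25	P25	0	0	1	1	.
FAM25	M25	0	0	2	1	.
FAM25	F25	P25	M25	1	2	.
FAM26	P26	0	0	1	1	.
FAM26	M26	0	0	2	1	.
FAM26	F26	P26	M26	1	2	.
FAM27	P27	0	0	1	1	.
FAM27	M27	0	0	2	1	.
FAM27	F27	P27	M27	2	2	.
FAM27	F33	P27	M27	2	2	.
FAM28	P28	0	0	1	1	.
FAM28	M28	0	0	2	1	.
FAM28	F28	P28	M28	2	2	.
FAM29	P29	0	0	1	1	.
FAM29	M29	0	0	2	1	.
FAM29	F29	P29	M29	2	2	.
FAM31	P31	0	0	1	1	.
FAM31	M31	0	0	2	1	.
FAM31	F31	P31	M31	2	2	.
FAM32	P32	0	0	1	1	.
FAM32	M32	0	0	2	1	.
FAM32	F32	P32	M32	2	2	.
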