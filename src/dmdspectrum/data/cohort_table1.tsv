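patient_id	ck	onset_age	wheelchair_age	current_age	phenotype	ihc	mlpa_call	validated_call
dmd1	4906	6	10	11	DMD	NA	del 46-48	NA
dmd4	4135	5	12	21	DMD	negative	no del/no dup	NA
dmd5	10499	5	10	12	DMD	negative	del 53-54	NA
dmd6	17388	4	ambulant	5	DMD	NA	del 46-50	NA
dmd8	2020	4	10	13	DMD	negative	del 17-43	NA
dmd9	3932	5	10	14	DMD	NA	del 45-52	NA
dmd10	11152	5	ambulant	7	DMD	faint	del 51	del 51
dmd11	16550	4	ambulant	8	DMD	faint	del 46-51	NA
dmd14	10846	5	ambulant	7	DMD	negative	no del/no dup	NA
dmd15	3125	8	ambulant	9	DMD	negative	del 48-50	NA
dmd16	8871	4	9	9	DMD	negative	del 45-52	NA
dmd17	6239	5	ambulant	6	DMD	negative	del 52	del 52
dmd18	3255	6	10	13	DMD	NA	del 65	small|c.9540-9551delCTGGCTGCTGAA|net=-12|stop=0|exon=65
dmd19	6924	5	ambulant	6	DMD	negative	dup 2-62	NA
dmd20	12948	7	ambulant	10	BMD	negative	del 7-43	NA
dmd21	28060	6	ambulant	7	DMD	negative	dup 2-62	NA
dmd22	NA	5	7	14	DMD	NA	no del/no dup	NA
dmd24	11433	5	ambulant	9	DMD	NA	del 47-50	NA
dmd25	NA	1	ambulant	6	DMD	NA	del 49-52	NA
dmd26	40429	6	ambulant	6	DMD	NA	no del/no dup	NA
dmd27	8961	6	ambulant	6	DMD	negative	no del/no dup	NA
dmd28	4137	9	ambulant	9	BMD	negative	del 47	small|c.6808delT|net=-1|stop=1|exon=47
dmd29	8340	5	9	18	DMD	NA	no del/no dup	NA
dmd30	8751	4	8	8	DMD	negative	del 51-54	NA
dmd31	9603	5	10	10	DMD	NA	del 3-44	NA
dmd33	7482	6	ambulant	9	DMD	NA	no del/no dup	NA
dmd34	6746	2	9	10	DMD	negative	del 49-50	NA
dmd35	15448	6	ambulant	9	DMD	faint	dup 14-17	NA
dmd36	6857	4	ambulant	8	DMD	negative	del 18-47	NA
dmd37	3337	5	ambulant	7	DMD	negative	del 56-74	NA
dmd38	6607	7	7	8	BMD	negative	del 45-49	NA
dmd39	2678	5	10	11	DMD	faint	del 18-34	NA
dmd42	1368	5	9	14	DMD	NA	dup 2-44	NA
dmd44	12324	5	ambulant	9	DMD	NA	del 48-52	NA
dmd47	13896	4	ambulant	6	DMD	NA	del 49-50	NA
dmd48	7800	2	13	14	DMD	NA	del 3-7	NA
dmd49	9569	9	ambulant	12	DMD	NA	del 3-7	NA
dmd50	7629	4	9	9	DMD	NA	del 5-7	NA
dmd51	7800	4	10	12	DMD	NA	del 3-17	NA
dmd53	4865	5	ambulant	9	DMD	negative	del 51	del 51
dmd54	1734	6	9	11	DMD	faint	dup 2-18	NA
dmd60	13100	5	ambulant	10	DMD	NA	del 49-52	NA
dmd61	11367	5	ambulant	9	DMD	NA	no del/no dup	NA
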