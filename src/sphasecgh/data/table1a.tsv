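# Per-cell BAC-probe counts passing the +/-0.3 log2-ratio threshold in the
# five constitutive regions of three carrier cell lines (transcribed counts).
# printed_flag: entry carries a published 'no call' mark; nocall_flag: the
# subset of those marks consistent with the published per-phase summary
# totals (narrated failed detections) and used for summary derivation.
cell_id	phase	cell_line	region	k	n	size_mb	direction	printed_flag	nocall_flag
S_1_1	S	1	dup7p	25	40	25.16	gain	0	0
S_1_2	S	1	dup7p	11	40	25.16	gain	0	0
S_1_3	S	1	dup7p	13	40	25.16	gain	0	0
S_1_4	S	1	dup7p	18	40	25.16	gain	0	0
S_1_5	S	1	dup7p	8	40	25.16	gain	1	0
S_1_6	S	1	dup7p	9	40	25.16	gain	1	0
S_1_7	S	1	dup7p	18	40	25.16	gain	0	0
S_1_8	S	1	dup7p	13	40	25.16	gain	0	0
S_1_9	S	1	dup7p	10	40	25.16	gain	1	1
S_1_10	S	1	dup7p	27	40	25.16	gain	0	0
G0/G1_1_1	G0G1	1	dup7p	23	40	25.16	gain	0	0
G0/G1_1_2	G0G1	1	dup7p	20	40	25.16	gain	0	0
G0/G1_1_3	G0G1	1	dup7p	18	40	25.16	gain	0	0
G0/G1_1_4	G0G1	1	dup7p	28	40	25.16	gain	0	0
G0/G1_1_5	G0G1	1	dup7p	24	40	25.16	gain	0	0
G0/G1_1_6	G0G1	1	dup7p	20	40	25.16	gain	0	0
G0/G1_1_7	G0G1	1	dup7p	25	40	25.16	gain	0	0
S_2_1	S	2	dup9p	26	42	24.0	gain	0	0
S_2_1	S	2	del18p	3	28	8.0	loss	1	1
S_2_2	S	2	dup9p	21	42	24.0	gain	0	0
S_2_2	S	2	del18p	13	28	8.0	loss	0	0
S_2_3	S	2	dup9p	19	42	24.0	gain	0	0
S_2_3	S	2	del18p	21	28	8.0	loss	0	0
S_2_4	S	2	dup9p	29	42	24.0	gain	0	0
S_2_4	S	2	del18p	20	28	8.0	loss	0	0
S_2_5	S	2	dup9p	22	42	24.0	gain	0	0
S_2_5	S	2	del18p	25	28	8.0	loss	0	0
S_2_6	S	2	dup9p	25	42	24.0	gain	0	0
S_2_6	S	2	del18p	18	28	8.0	loss	0	0
S_2_7	S	2	dup9p	28	42	24.0	gain	0	0
S_2_7	S	2	del18p	21	28	8.0	loss	0	0
S_2_8	S	2	dup9p	27	42	24.0	gain	0	0
S_2_8	S	2	del18p	22	28	8.0	loss	0	0
S_2_9	S	2	dup9p	18	42	24.0	gain	0	0
S_2_9	S	2	del18p	24	28	8.0	loss	0	0
S_2_10	S	2	dup9p	31	42	24.0	gain	0	0
S_2_10	S	2	del18p	22	28	8.0	loss	0	0
G0/G1_2_1	G0G1	2	dup9p	16	42	24.0	gain	0	0
G0/G1_2_1	G0G1	2	del18p	13	28	8.0	loss	0	0
G0/G1_2_2	G0G1	2	dup9p	19	42	24.0	gain	0	0
G0/G1_2_2	G0G1	2	del18p	17	28	8.0	loss	0	0
G0/G1_2_3	G0G1	2	dup9p	25	42	24.0	gain	0	0
G0/G1_2_3	G0G1	2	del18p	19	28	8.0	loss	0	0
G0/G1_2_4	G0G1	2	dup9p	36	42	24.0	gain	0	0
G0/G1_2_4	G0G1	2	del18p	23	28	8.0	loss	0	0
G0/G1_2_5	G0G1	2	dup9p	31	42	24.0	gain	0	0
G0/G1_2_5	G0G1	2	del18p	17	28	8.0	loss	0	0
G0/G1_2_6	G0G1	2	dup9p	23	42	24.0	gain	0	0
G0/G1_2_6	G0G1	2	del18p	20	28	8.0	loss	0	0
G0/G1_2_7	G0G1	2	dup9p	22	42	24.0	gain	0	0
G0/G1_2_7	G0G1	2	del18p	20	28	8.0	loss	0	0
G0/G1_2_8	G0G1	2	dup9p	31	42	24.0	gain	0	0
G0/G1_2_8	G0G1	2	del18p	19	28	8.0	loss	0	0
S_3_1	S	3	dup18p	7	30	9.3	gain	0	0
S_3_1	S	3	del20p	7	8	1.7	loss	0	0
S_3_2	S	3	dup18p	14	30	9.3	gain	0	0
S_3_2	S	3	del20p	7	8	1.7	loss	0	0
S_3_3	S	3	dup18p	4	30	9.3	gain	1	1
S_3_3	S	3	del20p	6	8	1.7	loss	0	0
S_3_4	S	3	dup18p	16	30	9.3	gain	0	0
S_3_4	S	3	del20p	7	8	1.7	loss	0	0
S_3_5	S	3	dup18p	11	30	9.3	gain	0	0
S_3_5	S	3	del20p	6	8	1.7	loss	0	0
S_3_6	S	3	dup18p	13	30	9.3	gain	0	0
S_3_6	S	3	del20p	8	8	1.7	loss	0	0
G0/G1_3_1	G0G1	3	dup18p	2	30	9.3	gain	1	1
G0/G1_3_1	G0G1	3	del20p	7	8	1.7	loss	0	0
G0/G1_3_2	G0G1	3	dup18p	17	30	9.3	gain	0	0
G0/G1_3_2	G0G1	3	del20p	6	8	1.7	loss	0	0
G0/G1_3_3	G0G1	3	dup18p	15	30	9.3	gain	0	0
G0/G1_3_3	G0G1	3	del20p	7	8	1.7	loss	0	0
G0/G1_3_4	G0G1	3	dup18p	19	30	9.3	gain	0	0
G0/G1_3_4	G0G1	3	del20p	5	8	1.7	loss	0	0
G0/G1_3_5	G0G1	3	dup18p	17	30	9.3	gain	0	0
G0/G1_3_5	G0G1	3	del20p	6	8	1.7	loss	0	0
G0/G1_3_6	G0G1	3	dup18p	17	30	9.3	gain	0	0
G0/G1_3_6	G0G1	3	del20p	7	8	1.7	loss	0	0
G0/G1_3_7	G0G1	3	dup18p	23	30	9.3	gain	0	0
G0/G1_3_7	G0G1	3	del20p	4	8	1.7	loss	0	0
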