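type_name	s1	s2	s3	s4	s5
I	9,10	12..17	19	20..24	3,13,14
II	7	13	8	21,23	6
IV	9,10,18	14..17	9,12,20	24	6..10,13
V	14	14	11	24	10
VII	6	14	12	27	8
VIII	6,9	12..14,16	12	25	8,9
XII	9,10	13,14	20,21	21	9,12,13
XIII	8,9	13..16	8,9,12,21	19,21..23,26,30	6..11,13
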