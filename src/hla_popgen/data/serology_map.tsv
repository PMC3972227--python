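# Serological split assignments for the B14, B15 and B40 broad groups.
# WHO-assigned serological equivalents of common full-resolution alleles;
# user-extensible. Alleles of these three groups that are absent here are
# rejected rather than silently truncated to the broad group.
allele	category
B*14:01	B*14(64)
B*14:02	B*14(65)
B*15:01	B*15(62)
B*15:02	B*15(75)
B*15:03	B*15(72)
B*15:04	B*15(62)
B*15:05	B*15(62)
B*15:06	B*15(62)
B*15:07	B*15(62)
B*15:08	B*15(75)
B*15:09	B*15(70)
B*15:10	B*15(71)
B*15:11	B*15(75)
B*15:12	B*15(76)
B*15:13	B*15(77)
B*15:15	B*15(62)
B*15:16	B*15(63)
B*15:17	B*15(63)
B*15:18	B*15(71)
B*15:20	B*15(62)
B*15:21	B*15(75)
B*15:25	B*15(62)
B*15:27	B*15(62)
B*15:28	B*15(75)
B*15:30	B*15(75)
B*15:31	B*15(75)
B*15:32	B*15(75)
B*15:33	B*15(75)
B*15:34	B*15(75)
B*15:35	B*15(62)
B*40:01	B*40(60)
B*40:02	B*40(61)
B*40:03	B*40(61)
B*40:06	B*40(61)
B*40:10	B*40(60)
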