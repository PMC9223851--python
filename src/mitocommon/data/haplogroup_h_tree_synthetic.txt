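# Synthetic haplogroup-H tree fixture: real clade names, signature
# motifs synthetic except H (universal set), H1=3010A, H3=6776C,
# H7=4793G, H23=10211T.
# Format: name<TAB>parent<TAB>signature tokens (root: empty parent)
H		263G 315.1C 750G 1438G 4769G 8860G 15326G 16519C
H1	H	3010A
H1aj	H1	601A
H1aj1	H1aj	638G
H1ax	H1	675G
H1bm	H1	712A
H1bw	H1	749G
H1c	H1	786C
H1c2	H1c	823C
H1e	H1	860A
H1e1	H1e	897A
H1e1a	H1e1	934A
H1e1a2	H1e1a	971C
H1e2	H1e	1008C
H1h	H1	1045A
H1h1	H1h	1082A
H1j	H1	1119A
H1j3	H1j	1156C
H1q	H1	1193C
H1q2	H1q	1230C
H1q3	H1q	1267A
H1r	H1	1304C
H1t	H1	1341G
H1u	H1	1378C
H1u1	H1u	1415A
H1w	H1	1452A
H2	H	1489C
H3	H	6776C
H3ag	H3	1526G
H3ap	H3	1563A
H3ar	H3	1600T
H3e	H3	1637C
H3q	H3	1674A
H7	H	4793G
H7a	H7	1711C
H7b	H7	1748A
H7b1	H7b	1785T
H7b6	H7b	1822T
H7c	H7	1859A
H7c2	H7c	1896G
H7d	H7	1933C
H7d3	H7d	1970C
H7e	H7	2007G
H10	H	2044G
H10a	H10	2081C
H10c	H10	2118G
H13	H	2155T
H13a	H13	2192G
H13a1	H13a	2229A
H13a1a	H13a1	2266T
H13a1a1	H13a1a	2303C
H13a2	H13a	2340T
H13a2a	H13a2	2377G
H17	H	2414T
H18	H	2451C
H18b	H18	2488G
H23	H	10211T
H26	H	2525A
H26a	H26	2562T
H26a1	H26a	2599A
H30	H	2636C
H30a	H30	2673A
H35	H	2710G
H51	H	2747G
H58	H	2784T
H59	H	2821A
H59a	H59	2858T
H64	H	2895C
H65	H	2932A
H72	H	2969T
H73	H	3006A
H75	H	3043T
H84	H	3080C
H86	H	3117A
H87	H	3154T
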