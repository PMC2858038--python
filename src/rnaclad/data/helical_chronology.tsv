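label	nd	archaea_A	archaea_M	bacteria_A	bacteria_B	bacteria_C	eukarya_E
P12	0.00	+	+	+	+	+	+
P1	0.05	+	+	+	+	+	+
P3	0.10	+	+	+	+	+	+
P4	0.15	+	+	+	+	+	+
P2	0.20	+	+	+	+	+	+
P10-11	0.25	+	+	+	+	+	+
P9	0.30	+	+	+	+	+	+
P8	0.35	+	-	+	+	+	+
P7	0.40	+	+	+	+	+	+
P5	0.45	+	+	+	+	+	+
P15	0.50	+	+	+	+	+	+
P6	0.55	+	-	+	-	+	-
P16	0.60	+	-	+	-	+	+
P17	0.65	+	-	+	-	+	-
P19	0.75	+	-	+	+	-	+
P13	0.75	-	-	+	-	-	-
P18	0.80	-	-	+	+	+	-
P16.1	0.80	+	-	+	-	-	-
P14	0.80	-	-	+	-	-	-
P16-17	0.85	-	-	+	-	-	-
P20	0.90	-	-	+	+	-	-
P15-16	0.90	+	-	-	-	-	-
P16.2	0.90	+	-	-	-	-	-
P5.1	0.95	-	-	-	+	-	-
P10.1	1.00	-	-	-	+	+	+
P15.1	1.00	-	-	-	+	+	-
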