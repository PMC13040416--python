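gene	acute_aerobic	acute_anaerobic	longterm_aerobic	longterm_resistance	other
ADD1	-0.29	-0.21	-0.27	-0.42	-0.50
ALAS2	0.78	-0.47	-0.49	-0.41	-0.37
ARF1	0.00	0.04	-0.19	-0.53	-0.42
ATP6V0C	0.00	0.08	-0.00	-0.54	-0.15
CA1	0.80	-0.31	-0.33	-0.30	-0.32
CCR7	0.68	-0.43	-0.21	-0.42	-0.25
CD3D	0.60	-0.44	0.01	-0.40	-0.08
CDK6	0.06	0.02	0.25	0.77	0.53
CENPE	0.69	-0.17	-0.36	0.00	-0.17
CTSE	0.74	-0.30	-0.30	-0.30	-0.30
EPB42	0.71	-0.42	-0.05	-0.31	-0.13
FEM1A	-0.27	-0.28	-0.48	-0.53	-0.70
GATA1	0.71	-0.41	0.15	-0.41	0.06
GYPB	0.78	-0.29	-0.29	-0.29	-0.29
GYPE	0.56	-0.27	-0.30	-0.21	-0.21
HBA1	0.53	0.51	-0.32	-0.50	-0.11
HBD	0.59	-0.45	-0.37	-0.28	-0.06
KIF18A	0.63	-0.18	-0.36	-0.09	-0.18
KRT1	0.75	-0.29	-0.32	-0.34	-0.21
LEF1	-0.05	0.71	-0.04	0.39	-0.64
LRRC8C	0.23	-0.04	0.13	0.61	0.52
MAP2K7	-0.29	-0.23	-0.27	-0.38	-0.51
MAP4K4	0.14	0.07	0.10	0.67	0.04
PICALM	0.53	0.30	0.19	0.43	0.58
RHAG	0.64	-0.24	-0.24	-0.24	-0.24
S1PR1	0.45	0.41	0.46	0.86	0.63
SIAH2	0.25	0.10	0.09	0.36	0.50
SLC4A1	0.79	-0.40	-0.40	-0.35	-0.34
SLC6A10P	0.05	-0.43	-0.57	0.54	-0.14
SNCA	0.66	-1.61	-0.55	0.75	0.14
STK11	-0.21	-0.14	-0.25	-0.43	-0.57
TAL1	0.25	0.05	0.17	0.58	0.40
TFR2	0.63	-0.43	0.05	-0.36	-0.05
TRIM58	0.75	-0.44	-0.38	-0.37	-0.40
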