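gene	acute_aerobic_mean	acute_aerobic_sd	acute_anaerobic_mean	acute_anaerobic_sd	longterm_aerobic_mean	longterm_aerobic_sd	longterm_resistance_mean	longterm_resistance_sd	other_mean	other_sd	inactivity_mean	inactivity_sd	p
GYPB	1.78	2.60	0.00	0.00	0.00	0.00	0.00	0.01	0.00	0.00	0.22	1.06	1.18e-38
CTSE	0.50	0.75	0.00	0.01	0.00	0.01	0.00	0.01	0.00	0.00	0.07	0.33	3.1e-30
RHAG	0.32	0.57	0.00	0.01	0.00	0.01	0.00	0.01	0.00	0.00	0.04	0.23	4.34e-30
SLC4A1	2.37	3.18	0.01	0.03	0.01	0.02	0.06	0.09	0.06	0.16	0.41	1.41	1.4e-20
ALAS2	3.36	4.32	0.06	0.10	0.03	0.11	0.14	0.21	0.19	0.43	0.72	1.97	1.94e-19
TRIM58	1.76	2.37	0.02	0.03	0.06	0.13	0.07	0.11	0.05	0.10	0.36	1.09	6.22e-16
HBA1	5.52	5.01	4.52	1.50	2.54	1.28	1.99	2.00	2.95	2.91	3.29	3.05	3.17e-15
SLC6A10P	0.26	0.37	0.10	0.14	0.06	0.09	0.54	0.65	0.19	0.23	0.24	0.43	5.55e-15
CA1	2.69	3.79	0.02	0.05	0.00	0.00	0.03	0.09	0.01	0.04	0.37	1.55	6.57e-14
CENPE	0.26	0.40	0.03	0.06	0.01	0.04	0.05	0.05	0.03	0.07	0.05	0.15	8.93e-14
TFR2	0.50	0.75	0.00	0.01	0.14	0.34	0.02	0.03	0.10	0.32	0.12	0.39	9.86e-13
FEM1A	7.21	0.20	7.20	0.26	7.16	0.22	7.15	0.22	7.10	0.25	7.27	0.23	3.38e-12
GATA1	1.49	2.08	0.01	0.03	0.48	1.08	0.01	0.02	0.39	1.02	0.32	1.05	4.33e-12
KRT1	1.58	2.26	0.05	0.20	0.03	0.15	0.02	0.03	0.09	0.55	0.26	0.98	4.38e-12
PICALM	5.21	0.44	5.11	0.48	5.06	0.55	5.15	0.37	5.24	0.46	4.96	0.50	3.82e-11
HBD	1.59	2.12	0.13	0.35	0.19	0.47	0.28	0.41	0.47	1.28	0.55	1.27	4.52e-10
STK11	4.37	0.28	4.39	0.27	4.36	0.29	4.32	0.24	4.27	0.29	4.43	0.27	6.06e-7
EPB42	1.71	2.38	0.08	0.06	0.35	0.47	0.16	0.09	0.28	0.52	0.39	1.04	1.05e-6
KIF18A	0.27	0.42	0.05	0.06	0.03	0.07	0.06	0.05	0.05	0.07	0.07	0.14	1.14e-6
ATP6V1D	4.06	0.23	4.04	0.24	4.08	0.24	4.08	0.21	4.12	0.22	4.01	0.23	1.32e-5
TPM1	11.19	0.50	11.40	0.49	11.37	0.44	11.48	0.50	11.40	0.42	11.34	0.47	1.47e-5
ARF1	6.34	0.22	6.35	0.23	6.30	0.21	6.23	0.20	6.25	0.21	6.34	0.21	1.48e-5
SH3GL1	2.69	0.64	2.70	0.52	2.59	0.64	2.63	0.66	2.70	0.69	2.49	0.62	5.1e-5
GYPE	0.62	1.11	0.05	0.07	0.04	0.06	0.07	0.07	0.07	0.10	0.14	0.46	1.04e-4
WDTC1	4.41	0.24	4.42	0.25	4.44	0.22	4.38	0.24	4.37	0.29	4.47	0.24	1.2e-4
FBXO30	1.71	0.32	1.63	0.33	1.63	0.38	1.71	0.28	1.65	0.37	1.60	0.33	1.21e-4
KIF23	0.18	0.32	0.05	0.10	0.15	0.29	0.08	0.09	0.14	0.29	0.08	0.19	1.35e-4
FBXO9	4.02	0.55	3.98	0.64	3.99	0.63	4.06	0.51	3.88	0.98	4.15	0.56	7.06e-4
UBQLN1	4.42	0.24	4.42	0.26	4.35	0.23	4.36	0.19	4.36	0.29	4.35	0.25	1.67e-3
ANKRD9	5.54	0.42	5.54	0.47	5.42	0.37	5.43	0.43	5.41	0.51	5.43	0.41	2.26e-3
NEDD4L	2.74	0.47	2.68	0.46	2.61	0.46	2.79	0.50	2.81	0.44	2.81	0.48	2.46e-3
RBL1	1.81	0.29	1.75	0.34	1.81	0.29	1.88	0.27	1.76	0.31	1.86	0.30	2.72e-3
GMPR	6.24	0.26	6.27	0.31	6.25	0.29	6.18	0.24	6.21	0.36	6.26	0.26	4.15e-3
ABCG2	0.11	0.13	0.12	0.15	0.13	0.13	0.17	0.13	0.15	0.16	0.12	0.12	6.59e-3
PSME4	3.94	0.28	3.93	0.32	3.88	0.29	4.02	0.27	3.91	0.27	3.89	0.31	8.0e-3
FBXL4	1.70	0.31	1.68	0.35	1.68	0.34	1.82	0.31	1.70	0.35	1.75	0.34	1.29e-2
SKI	2.69	0.52	2.60	0.55	2.58	0.54	2.76	0.46	2.62	0.56	2.56	0.55	1.37e-2
EPN1	5.24	0.29	5.27	0.24	5.25	0.26	5.26	0.27	5.19	0.30	5.29	0.25	1.96e-2
ISCA1	4.81	0.33	4.83	0.35	4.82	0.37	4.90	0.30	4.81	0.37	4.77	0.34	2.66e-2
AQP1	0.00	0.00	0.01	0.03	0.00	0.02	0.00	0.01	0.00	0.01	0.00	0.03	2.91e-2
AP2B1	3.90	0.30	3.87	0.29	3.91	0.30	3.89	0.27	3.96	0.27	3.87	0.27	3.84e-2
HBB	9.71	1.81	10.10	1.84	8.96	2.56	9.48	2.10	9.94	1.98	9.72	1.92	NaN
UBA52	8.42	1.06	8.64	0.70	8.60	0.55	8.43	0.82	8.24	1.42	8.39	1.03	NaN
SLC25A37	7.55	1.43	7.15	1.50	7.08	1.42	7.34	1.26	7.15	1.66	7.23	1.52	NaN
SLC25A39	7.35	1.95	6.94	1.82	7.43	1.14	7.65	1.44	7.67	1.60	7.43	1.47	NaN
BLVRB	6.33	1.26	6.12	1.34	6.16	1.70	6.07	1.21	6.27	1.46	6.06	1.57	NaN
ATP6V0C	6.15	0.94	6.24	1.07	6.14	1.20	5.48	1.44	5.99	1.13	6.15	0.98	NaN
CTSB	5.50	0.61	5.53	0.52	5.49	0.59	5.53	0.54	5.41	0.62	5.43	0.59	NaN
PCGF5	5.00	1.50	5.02	1.41	4.73	1.64	5.45	1.22	5.33	1.18	4.80	1.51	NaN
STRADB	4.86	1.12	4.95	1.12	4.61	1.54	4.97	0.99	4.76	1.30	5.03	1.08	NaN
PSMF1	4.93	0.71	4.99	0.64	5.06	0.57	4.90	0.69	5.03	0.66	4.98	0.74	NaN
FBXO7	5.00	1.24	4.74	1.36	5.19	1.13	4.69	1.38	4.99	1.17	4.71	1.46	NaN
BCL2L1	4.67	1.55	4.55	1.39	4.65	1.32	4.48	1.43	4.68	1.66	3.99	1.78	NaN
LGALS3	4.04	1.36	4.11	1.21	4.14	1.41	4.33	1.21	4.40	1.10	4.13	1.21	NaN
TFRC	3.95	0.84	3.89	0.98	3.86	0.89	3.77	0.68	3.83	0.77	4.00	0.82	NaN
FECH	3.33	0.94	3.45	0.85	3.34	0.89	3.69	0.53	3.45	0.74	3.47	0.78	NaN
FCHO2	2.15	0.71	2.10	0.72	2.05	0.89	2.16	0.63	2.17	0.81	2.05	0.87	NaN
CD3G	1.49	1.16	1.34	1.14	1.09	1.33	1.66	0.82	1.22	1.17	1.58	0.95	NaN
TAL1	1.32	1.27	1.04	1.48	1.24	1.59	1.73	1.00	1.52	1.20	0.96	1.57	NaN
KLC3	0.54	1.08	0.55	1.16	0.08	0.86	-0.23	1.90	-0.56	2.26	-0.03	1.49	NaN
RBM38	6.24	0.86	6.23	0.83	6.16	0.78	6.15	0.74	6.10	0.76	6.43	0.74	NaN
SNCA	5.47	0.86	2.42	1.31	3.83	1.56	5.51	0.59	4.85	0.91	4.67	1.47	NaN
SELENBP1	4.36	1.47	4.46	1.63	4.46	1.01	4.29	1.08	4.19	1.31	4.61	1.30	NaN
BPGM	3.40	1.16	3.47	1.19	3.38	1.44	2.84	1.39	3.18	1.28	3.46	1.27	NaN
TENT5C	2.95	1.59	2.67	1.75	3.17	1.61	2.80	1.46	3.07	1.50	3.24	1.24	NaN
MARCHF8	2.64	1.32	2.69	1.24	2.83	1.24	3.24	0.78	2.69	1.25	3.00	1.27	NaN
SIAH2	2.92	1.24	2.73	1.17	2.72	1.18	3.00	0.96	3.14	0.88	2.60	1.24	NaN
OSBP2	1.45	1.63	1.28	1.62	1.67	1.29	1.56	1.53	1.10	1.99	1.74	1.29	NaN
E2F2	0.26	0.80	0.63	0.82	0.66	0.49	0.76	0.57	0.58	0.75	0.49	0.67	NaN
CDK4	3.18	0.35	3.17	0.35	3.16	0.37	3.12	0.41	3.18	0.37	3.09	0.36	3.13e-3
MAPKAPK5	2.83	0.26	2.83	0.26	2.81	0.26	2.81	0.23	2.75	0.27	2.86	0.26	6.94e-3
GUK1	6.94	1.29	6.24	2.02	6.22	1.99	6.46	1.86	6.99	1.19	6.41	1.61	NaN
CD28	0.94	0.75	1.05	0.53	0.76	0.60	0.99	0.51	0.98	0.60	0.92	0.57	NaN
DCTD	3.20	0.33	3.25	0.30	3.24	0.31	3.34	0.28	3.21	0.37	3.24	0.31	3.59e-2
MAP4K4	3.56	0.55	3.52	0.51	3.54	0.59	3.83	0.43	3.51	0.83	3.48	0.59	NaN
BRD4	3.82	1.05	3.74	1.21	3.53	1.53	3.69	1.15	3.62	1.38	3.43	1.32	NaN
LRRC8C	1.48	0.44	1.36	0.48	1.44	0.49	1.62	0.35	1.61	0.45	1.38	0.43	4.26e-8
CDK6	0.84	0.51	0.82	0.46	0.93	0.49	1.13	0.39	1.05	0.46	0.81	0.44	1.53e-10
TNRC6A	2.94	0.49	2.89	0.51	2.85	0.55	2.93	0.41	2.83	0.57	2.89	0.47	NaN
PSENEN	3.58	0.66	3.53	0.89	3.64	0.62	3.56	0.74	3.66	0.72	3.58	0.73	NaN
TNRC6C	1.96	0.77	1.83	0.79	1.76	0.85	1.87	0.65	1.74	0.76	1.92	0.99	NaN
RPS27A	7.77	1.26	7.66	1.30	7.79	0.89	7.54	1.22	7.61	1.27	7.74	1.14	NaN
JUN	5.16	0.81	5.20	0.59	5.01	0.70	4.95	1.01	4.95	1.01	5.04	0.79	NaN
S1PR1	3.29	0.68	3.27	0.71	3.29	0.63	3.52	0.52	3.42	0.68	2.97	0.73	NaN
DMTN	5.39	1.22	5.24	1.47	5.25	1.64	5.51	1.26	5.28	1.46	5.30	1.47	NaN
MAP2K7	3.72	0.32	3.74	0.30	3.73	0.29	3.69	0.33	3.65	0.32	3.81	0.30	1.26e-6
PHC1	1.30	0.35	1.27	0.38	1.29	0.37	1.49	0.30	1.30	0.39	1.32	0.38	2.08e-4
ADD1	5.32	0.28	5.34	0.28	5.33	0.24	5.29	0.25	5.26	0.29	5.40	0.27	3.33e-6
FKBP8	7.20	1.41	7.07	1.37	7.25	1.13	6.92	1.70	7.17	1.14	7.36	1.43	NaN
SLC6A8	5.11	0.31	5.09	0.33	5.03	0.33	4.96	0.28	5.07	0.33	4.95	0.34	2.55e-9
MAPKAPK2	5.48	0.23	5.47	0.27	5.41	0.25	5.41	0.24	5.42	0.28	5.42	0.28	3.63e-2
UBB	9.14	1.00	9.19	1.05	9.10	1.22	8.95	1.05	8.75	1.43	9.27	1.03	NaN
IFI27	3.99	0.96	3.77	1.23	4.29	0.78	4.20	0.77	4.30	0.87	3.82	1.10	NaN
RAP1GAP	0.46	0.99	0.01	0.04	0.07	0.17	0.02	0.03	0.04	0.12	0.09	0.43	2.96e-8
YOD1	2.03	1.44	1.57	1.79	2.23	1.25	1.84	1.64	1.62	1.66	1.74	1.62	NaN
CCR7	2.16	2.88	0.08	0.12	0.31	0.61	0.09	0.10	0.27	0.46	0.57	1.59	8.9e-4
EEF1D	7.83	0.53	7.77	0.60	7.78	0.5	7.65	0.48	7.74	0.68	7.86	0.52	2.95e-3
TNS1	4.96	0.45	4.95	0.60	4.93	0.46	4.80	0.49	4.82	0.69	4.89	0.50	2.32e-2
ADIPOR1	5.99	1.28	5.97	1.31	6.05	1.28	6.15	1.20	5.98	1.34	6.15	1.30	NaN
UBXN6	5.63	0.91	5.64	0.96	5.64	0.77	5.65	1.10	5.61	1.06	5.70	0.82	NaN
MIF	4.20	0.78	4.24	0.63	4.20	0.69	4.30	0.61	4.18	0.98	4.17	0.75	NaN
CD247	2.31	1.50	2.23	1.77	2.41	1.56	2.79	0.89	2.94	1.20	2.47	1.46	NaN
LEF1	2.53	1.46	3.37	0.75	2.56	1.16	3.08	1.05	1.76	1.33	2.61	1.31	NaN
SKAP1	1.19	1.33	1.01	1.63	1.39	1.73	1.63	0.87	1.50	1.10	1.33	1.22	NaN
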