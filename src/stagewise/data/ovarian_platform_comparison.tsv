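gene	illumina_rank	illumina_fold	illumina_p	affymetrix_rank	affymetrix_fold	affymetrix_p
ACTA1
ACTA2	1.8	-7.7	2.00E-06	0.6	-58.8	5.00E-05
ACTG1	5.7	-1.8	6.00E-05
ACTG2
ACTN1	2.7	-2.6	5.00E-06	0.5	-4.0	2.00E-05
FBLIM1	1.4	-2.3	8.00E-07	0.8	-8.3	9.00E-05
ITGA7				5.3	-5.0	2.00E-02
ITGAV				4.8	-2.4	1.00E-02
ITGB1				0.8	-5.3	1.00E-04
ITGB2
ITGB5	1.6	-6.3	1.00E-06	0.7	-4.5	5.00E-05
LASP1
MARCKS	0.5	-10.2	3.00E-08	1.4	-7.1	5.00E-04
NCK2	5.5	-1.9	6.00E-05
PARVA	9.4	-1.8	3.00E-04	2.9	-4.5	4.00E-03
PXN
TGFB1I1	7.3	-6.7	1.00E-04
TNS1	7.8	-2.9	2.00E-04	4.3	-7.1	1.00E-02
TPM2	0.03	-23.1	1.00E-11	1.9	-7.0	1.00E-03
VCL	8.1	-2.0	2.00E-04
ZYX	8.7	-1.9	2.00E-04	1.3	-3.6	4.00E-04
NDN	0.5	-124.6	3.00E-11	0.3	-23.7	5.0E-06
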