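Gene symbol	Coefficient	Tissue
Intercept	49.1
RF00019	-0.5534609	Pituitary
RASSF8	0.43450456	Pituitary
ALOX15B	0.42384809	Pituitary
IGSF1	-0.3815586	Pituitary
MAOA	0.3779751	Pituitary
PIGP	-0.3643882	Pituitary
AC138904.1	-0.3590232	Pituitary
ITGA10	0.34749327	Pituitary
CYP51A1P2	-0.3468059	Pituitary
FABP6	0.33526575	Pituitary
AC007938.1	-0.3287363	Pituitary
LINC01315	-0.3252791	Pituitary
AL596325.2	0.32297086	Pituitary
LINC00662	0.3151238	Muscle
CATSPERB	0.31335041	Pituitary
MUC1	0.31188538	Pituitary
NBEAP3	0.29659649	Pituitary
SNAI3	-0.2943786	Pituitary
HIST1H1C	0.29287356	Pituitary
LINC02232	0.28356117	Pituitary
S100A1	0.28252535	Pituitary
KMO	0.27801131	Pituitary
HLA-DOB	0.27540573	Pituitary
AC124947.1	0.26677666	Pituitary
KCNK4	-0.2667203	Pituitary
HMGN2P46	-0.265154	Pituitary
AIPL1	-0.262319	Pituitary
AC079922.1	-0.2613869	Pituitary
CYP3A5	0.25593725	Pituitary
MIR3186	-0.248713	Pituitary
FA2H	-0.2478653	Pituitary
LZTS1	-0.2453074	Pituitary
FKBP5	-0.2403517	Pituitary
HTN3	0.23757784	Pituitary
VNN3	0.23713188	Pituitary
MMP11	-0.2370928	Pituitary
PADI2	0.23575174	Pituitary
NANOGNBP3	0.23556292	Pituitary
ST6GALNAC5	-0.2348075	Pituitary
C7	-0.2308648	Pituitary
KCNMB2-AS1	0.22953261	Pituitary
DQX1	-0.2276446	Pituitary
GSTM4	0.22188874	Pituitary
AC021016.1	0.22063205	Pituitary
FER1L4	0.2180329	Pituitary
LY6G5B	0.21750613	Pituitary
ZBTB16	-0.2170829	Pituitary
FCF1P1	-0.2147114	Pituitary
CHRNA1	0.21457823	Pituitary
MGAT5	-0.2125122	Pituitary
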