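name	x	y	z
FC5	-0.765784	0.300013	0.568829
FC3	-0.554657	0.304851	0.774223
FC1	-0.291089	0.307950	0.905778
FCZ	0.000000	0.309017	0.951057
FC2	0.291089	0.307950	0.905778
FC4	0.554657	0.304851	0.774223
FC6	0.765784	0.300013	0.568829
C5	-0.809017	0.000000	0.587785
C3	-0.587785	0.000000	0.809017
C1	-0.309017	0.000000	0.951057
CZ	-0.000000	0.000000	1.000000
C2	0.309017	0.000000	0.951057
C4	0.587785	0.000000	0.809017
C6	0.809017	0.000000	0.587785
CP5	-0.765784	-0.300013	0.568829
CP3	-0.554657	-0.304851	0.774223
CP1	-0.291089	-0.307950	0.905778
CPZ	0.000000	-0.309017	0.951057
CP2	0.291089	-0.307950	0.905778
CP4	0.554657	-0.304851	0.774223
CP6	0.765784	-0.300013	0.568829
FP1	-0.293893	0.904508	0.309017
FPZ	0.000000	0.951057	0.309017
FP2	0.293893	0.904508	0.309017
AF7	-0.559017	0.769421	0.309017
AF3	-0.312961	0.798559	0.514158
AFZ	0.000000	0.809017	0.587785
AF4	0.312961	0.798559	0.514158
AF8	0.559017	0.769421	0.309017
F7	-0.769421	0.559017	0.309017
F5	-0.640707	0.570783	0.513519
F3	-0.459031	0.579960	0.673006
F1	-0.239410	0.585788	0.774297
FZ	0.000000	0.587785	0.809017
F2	0.239410	0.585788	0.774297
F4	0.459031	0.579960	0.673006
F6	0.640707	0.570783	0.513519
F8	0.769421	0.559017	0.309017
FT7	-0.904508	0.293893	0.309017
FT8	0.904508	0.293893	0.309017
T7	-0.951057	0.000000	0.309017
T8	0.951057	0.000000	0.309017
T9	-1.000000	0.000000	0.000000
T10	1.000000	0.000000	0.000000
TP7	-0.904508	-0.293893	0.309017
TP8	0.904508	-0.293893	0.309017
P7	-0.769421	-0.559017	0.309017
P5	-0.640707	-0.570783	0.513519
P3	-0.459031	-0.579960	0.673006
P1	-0.239410	-0.585788	0.774297
PZ	0.000000	-0.587785	0.809017
P2	0.239410	-0.585788	0.774297
P4	0.459031	-0.579960	0.673006
P6	0.640707	-0.570783	0.513519
P8	0.769421	-0.559017	0.309017
PO7	-0.559017	-0.769421	0.309017
PO3	-0.312961	-0.798559	0.514158
POZ	0.000000	-0.809017	0.587785
PO4	0.312961	-0.798559	0.514158
PO8	0.559017	-0.769421	0.309017
O1	-0.293893	-0.904508	0.309017
OZ	0.000000	-0.951057	0.309017
O2	0.293893	-0.904508	0.309017
IZ	0.000000	-1.000000	0.000000
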