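locus	outcome	odds_ratio	estimate	se	pvalue	ci_low	ci_high	egger_intercept	egger_intercept_pvalue
JMJD1C	alzheimers	0.875	-0.133	0.145	0.359				
JMJD1C	bipolar	1.402	0.338	0.234	0.149				
JMJD1C	schizophrenia	1.132	0.124	0.182	0.496				
JMJD1C	depression	0.984	-0.016	0.02	0.437				
JMJD1C	rheumatoid_arthritis	1.69	0.525	0.226	0.020	0.083	0.967		
JMJD1C	gout	0.469	-0.757	0.221	0.001	-1.189	-0.324		
JMJD1C	type2_diabetes	0.769	-0.262	0.133	0.048	-0.522	-0.002		
SHBG	alzheimers	0.998	-0.002	0.029	0.935			0.013	0.015
SHBG	bipolar	0.991	-0.009	0.085	0.920			0.007	0.664
SHBG	schizophrenia	1.038	0.038	0.053	0.176			-0.004	0.672
SHBG	depression	1.02	0.02	0.006	0.001	0.008	0.031	0.002	0.092
SHBG	rheumatoid_arthritis	1.329	0.285	0.06	<0.001	0.141	0.429	0.022	0.120
SHBG	gout	0.971	-0.029	0.064	0.649			0.005	0.683
SHBG	type2_diabetes	0.887	-0.119	0.03	0.003	-0.203	-0.035	-0.027	0.607
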