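family	model	split	TP	FN	TN	FP	SE	SP	Q_i	Q_ni	C	AUC
RP	MP	training	637	140	143	44	0.820	0.765	0.935	0.505	0.508	0.846
RP	MP	test	196	42	53	9	0.824	0.855	0.956	0.558	0.590	0.851
RP	MP+ECFP_4	training	709	68	177	10	0.912	0.947	0.986	0.722	0.780	0.946
RP	MP+ECFP_4	test	210	28	56	6	0.882	0.903	0.972	0.667	0.708	0.898
RP	MP+ECFP_6	training	709	68	177	10	0.912	0.947	0.986	0.722	0.780	0.946
RP	MP+ECFP_6	test	210	28	58	4	0.882	0.935	0.981	0.674	0.732	0.917
RP	MP+EPFP_4	training	707	70	177	10	0.910	0.947	0.986	0.717	0.776	0.980
RP	MP+EPFP_4	test	213	25	53	9	0.895	0.855	0.959	0.679	0.692	0.941
RP	MP+EPFP_6	training	714	63	178	9	0.919	0.952	0.988	0.739	0.795	0.974
RP	MP+EPFP_6	test	220	18	52	10	0.924	0.839	0.957	0.743	0.731	0.873
RP	MP+FCFP_4	training	715	62	178	9	0.920	0.952	0.988	0.742	0.797	0.959
RP	MP+FCFP_4	test	216	22	56	6	0.908	0.903	0.973	0.718	0.748	0.917
RP	MP+FCFP_6	training	699	78	176	11	0.900	0.941	0.985	0.693	0.755	0.945
RP	MP+FCFP_6	test	216	22	56	6	0.908	0.903	0.973	0.718	0.748	0.929
RP	MP+FPFP_4	training	710	67	178	9	0.914	0.952	0.987	0.727	0.786	0.982
RP	MP+FPFP_4	test	216	22	57	5	0.908	0.919	0.977	0.722	0.760	0.937
RP	MP+FPFP_6	training	704	73	176	11	0.906	0.941	0.985	0.707	0.765	0.944
RP	MP+FPFP_6	test	215	23	53	9	0.903	0.855	0.960	0.697	0.706	0.891
RP	MP+LCFP_4	training	692	85	170	17	0.891	0.909	0.976	0.667	0.717	0.942
RP	MP+LCFP_4	test	210	28	52	10	0.882	0.839	0.955	0.650	0.660	0.895
RP	MP+LCFP_6	training	692	85	170	17	0.891	0.909	0.976	0.667	0.717	0.942
RP	MP+LCFP_6	test	210	28	52	10	0.882	0.839	0.955	0.650	0.660	0.995
RP	MP+LPFP_4	training	709	68	177	10	0.912	0.947	0.986	0.722	0.780	0.966
RP	MP+LPFP_4	test	206	32	55	7	0.866	0.887	0.967	0.632	0.672	0.903
RP	MP+LPFP_6	training	709	68	171	16	0.912	0.914	0.978	0.715	0.757	0.943
RP	MP+LPFP_6	test	210	28	55	7	0.882	0.887	0.968	0.663	0.696	0.895
NB	MP	training	673	140	121	66	0.828	0.647	0.911	0.464	0.422	0.772
NB	MP	test	163	75	48	14	0.685	0.774	0.921	0.390	0.378	0.794
NB	MP+ECFP_4	training	730	47	174	13	0.940	0.930	0.983	0.787	0.818	0.958
NB	MP+ECFP_4	test	205	33	59	3	0.861	0.952	0.986	0.641	0.714	0.970
NB	MP+ECFP_6	training	731	46	177	10	0.941	0.947	0.987	0.794	0.832	0.959
NB	MP+ECFP_6	test	214	24	58	4	0.899	0.935	0.982	0.707	0.758	0.971
NB	MP+EPFP_4	training	713	64	157	30	0.918	0.840	0.960	0.710	0.712	0.921
NB	MP+EPFP_4	test	185	53	54	8	0.777	0.871	0.959	0.505	0.548	0.916
NB	MP+EPFP_6	training	662	115	179	8	0.852	0.957	0.988	0.609	0.695	0.932
NB	MP+EPFP_6	test	190	48	56	6	0.798	0.903	0.969	0.538	0.597	0.945
NB	MP+FCFP_4	training	699	78	174	13	0.900	0.930	0.982	0.690	0.747	0.955
NB	MP+FCFP_4	test	206	32	57	5	0.866	0.919	0.976	0.640	0.696	0.96
NB	MP+FCFP_6	training	722	55	176	11	0.929	0.941	0.985	0.762	0.806	0.958
NB	MP+FCFP_6	test	209	29	57	5	0.878	0.919	0.977	0.663	0.714	0.967
NB	MP+FPFP_4	training	698	79	164	23	0.898	0.877	0.968	0.675	0.706	0.926
NB	MP+FPFP_4	test	187	51	57	5	0.786	0.919	0.974	0.528	0.595	0.934
NB	MP+FPFP_6	training	687	90	168	19	0.884	0.898	0.973	0.651	0.699	0.932
NB	MP+FPFP_6	test	188	50	57	5	0.790	0.919	0.974	0.533	0.600	0.952
NB	MP+LCFP_4	training	721	56	176	11	0.928	0.941	0.985	0.759	0.804	0.958
NB	MP+LCFP_4	test	209	29	59	3	0.878	0.952	0.986	0.670	0.738	0.965
NB	MP+LCFP_6	training	718	59	180	7	0.924	0.963	0.990	0.753	0.812	0.957
NB	MP+LCFP_6	test	215	23	58	4	0.903	0.935	0.982	0.716	0.765	0.965
NB	MP+LPFP_4	training	661	116	180	7	0.851	0.963	0.990	0.608	0.697	0.948
NB	MP+LPFP_4	test	204	34	59	3	0.857	0.952	0.986	0.634	0.708	0.964
NB	MP+LPFP_6	training	695	82	180	7	0.894	0.963	0.990	0.687	0.762	0.949
NB	MP+LPFP_6	test	206	32	58	4	0.866	0.935	0.981	0.644	0.708	0.969
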