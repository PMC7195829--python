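property	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
hydropathy	-0.027	1.24	3.627	3.7	0.984	5.505	2.213	4.243	0.726	0.537	3.279	1.781	2.97	1.24	2.312	0.134	-2.702	0.818	3.059	2.839
polarity	5.606	6.748	3.499	2.889	5.05	1.649	8.905	4.898	6.959	1.996	3.292	7.305	4.196	5.466	5.759	0.03	7.321	2.283	2.546	5.875
isoelectric_point	0.527	-2.011	-0.614	2.186	3.294	0.847	0.186	1.63	3.09	3.755	0.156	-0.85	0.392	-3.965	0.6	1.411	-2.187	4.048	1.253	0.08
volume	2.446	1.371	1.961	1.37	2.486	0.885	3.122	1.126	1.932	3.004	0.955	1.986	0.972	4.489	4.622	1.866	2.626	0.444	2.723	1.827
bulkiness	1.761	-3.075	0.904	2.847	-0.194	2.711	0.268	0.726	-3.414	-2.883	0.083	-2.968	1.395	1.771	4.687	0.741	4.045	0.339	-3.746	0.362
flexibility	1.744	1.056	3.298	3.015	1.805	1.978	2.106	1.14	1.263	2.379	3.248	1.523	3.15	2.783	1.472	1.5	2.029	3.708	2.265	2.371
refractivity	5.232	0.323	0.907	7.55	6.8	2.965	2.904	0.463	5.916	6.037	0.928	4.761	3.731	2.129	0.473	5.201	4.789	0.954	4.835	5.144
mutability	6.277	4.634	4.988	5.684	4.965	4.755	4.574	3.983	4.937	4.152	5.216	5.158	3.191	5.246	5.493	5.524	5.154	5.922	2.994	5.161
helix_propensity	4.381	3.505	2.653	3.375	4.309	3.724	4.704	3.94	4.191	3.818	4.385	3.402	5.338	5.497	4.939	4.842	5.12	5.091	4.763	4.52
sheet_propensity	-1.481	-2.223	-2.098	-2.078	-1.067	-2.657	-1.61	-1.946	-1.432	-0.393	-2.411	-2.157	-0.895	-1.846	-1.878	-0.416	-2.271	-1.318	-1.141	-1.33
turn_propensity	3.674	5.816	0.872	4.028	2.77	6.185	4.411	1.434	1.426	9.794	6.812	3.283	10.001	2.053	-0.33	6.141	3.566	3.624	1.591	3.792
coil_propensity	-1.466	7.854	5.035	-0.5	3.554	1.329	0.692	-0.809	5.586	7.752	3.188	2.889	4.129	4.011	1.054	-1.652	1.051	2.778	1.996	2.421
buried_fraction	-0.196	-1.327	-2.727	-0.268	-3.046	0.365	-0.271	-2.647	-2.693	-2.866	-0.789	-0.499	1.66	-1.679	-2.481	-1.008	-1.429	1.222	-2.25	-0.765
accessible_surface	3.483	2.522	1.071	3.938	4.625	4.309	0.479	2.369	2.912	4.642	2.023	-1.198	3.199	2.953	1.62	3.54	2.331	5.59	5.182	7.65
transfer_energy	5.874	5.385	4.019	4.05	3.903	4.098	5.097	3.585	2.904	2.722	3.588	5.192	5.01	2.781	4.459	4.434	3.589	4.293	2.546	4.394
hydration_potential	1.703	0.833	0.939	1.224	1.797	0.305	1.757	-0.582	-0.589	2.93	1.516	0.367	1.075	1.121	0.827	0.814	1.367	1.256	-0.33	0.697
net_charge_index	3.496	6.558	8.217	1.35	7.045	8.867	1.05	6.969	3.21	3.816	7.834	10.712	7.015	7.298	3.943	5.593	3.589	7.457	2.186	2.885
polarizability	0.275	-0.088	5.702	-1.363	1.674	-1.252	4.904	0.525	5.755	-0.289	-1.247	-0.124	0.353	7.166	-5.574	1.032	-4.275	1.482	2.363	1.125
partition_coefficient	2.226	3.998	1.6	1.148	2.422	1.027	3.621	2.194	3.738	2.186	4.267	4.24	3.5	4.288	3.544	4.59	2.133	2.061	2.558	3.625
compressibility	0.363	0.112	2.602	-0.837	3.381	0.717	1.416	3.982	3.105	-2.099	2.456	2.214	-1.295	2.437	-0.12	-0.676	-0.722	0.117	-1.125	-0.252
side_chain_mass	4.806	2.611	5.463	6.222	6.961	3.224	0.238	2.317	7.078	6.245	1.446	2.303	6.717	6.228	4.471	2.553	2.055	4.661	6.277	2.687
entropy_of_formation	3.761	3.696	4.73	3.705	3.773	2.381	3.998	3.596	3.113	4.833	5.562	2.733	5.577	3.269	3.864	3.32	2.96	1.609	4.495	2.629
alpha_CH_shift	3.917	4.669	3.952	4.404	3.606	4.439	4.932	6.201	4.593	5.396	3.655	4.791	3.128	4.491	4.171	4.494	5.215	4.285	4.506	4.701
heat_capacity	3.253	2.656	-1.631	-1.517	-1.576	-1.945	-1.272	-0.944	-4.586	-7.802	1.817	-1.582	-3.684	-0.656	0.914	3.614	-6.731	-1.821	-0.152	1.258
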