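oxphos	oxphos gene set	G00001	G00002	G00003	G00004	G00005	G00006	G00007	G00008	G00009	G00010	G00011	G00012	G00013	G00014	G00015	G00016	G00017	G00018	G00019	G00020
glycolysis	glycolysis gene set	G00021	G00022	G00023	G00024	G00025	G00026	G00027	G00028	G00029	G00030	G00031	G00032	G00033	G00034	G00035	G00036	G00037	G00038	G00039	G00040
tca_cycle	tca_cycle gene set	G00041	G00042	G00043	G00044	G00045	G00046	G00047	G00048	G00049	G00050	G00051	G00052	G00053	G00054	G00055	G00056	G00057	G00058	G00059	G00060
fatty_acid_oxidation	fatty_acid_oxidation gene set	G00061	G00062	G00063	G00064	G00065	G00066	G00067	G00068	G00069	G00070	G00071	G00072	G00073	G00074	G00075	G00076	G00077	G00078	G00079	G00080
fatty_acid_synthesis	fatty_acid_synthesis gene set	G00081	G00082	G00083	G00084	G00085	G00086	G00087	G00088	G00089	G00090	G00091	G00092	G00093	G00094	G00095	G00096	G00097	G00098	G00099	G00100
pentose_phosphate	pentose_phosphate gene set	G00101	G00102	G00103	G00104	G00105	G00106	G00107	G00108	G00109	G00110	G00111	G00112	G00113	G00114	G00115	G00116	G00117	G00118	G00119	G00120
glutaminolysis	glutaminolysis gene set	G00121	G00122	G00123	G00124	G00125	G00126	G00127	G00128	G00129	G00130	G00131	G00132	G00133	G00134	G00135	G00136	G00137	G00138	G00139	G00140
one_carbon_metabolism	one_carbon_metabolism gene set	G00141	G00142	G00143	G00144	G00145	G00146	G00147	G00148	G00149	G00150	G00151	G00152	G00153	G00154	G00155	G00156	G00157	G00158	G00159	G00160
serine_biosynthesis	serine_biosynthesis gene set	G00161	G00162	G00163	G00164	G00165	G00166	G00167	G00168	G00169	G00170	G00171	G00172	G00173	G00174	G00175	G00176	G00177	G00178	G00179	G00180
nucleotide_synthesis	nucleotide_synthesis gene set	G00181	G00182	G00183	G00184	G00185	G00186	G00187	G00188	G00189	G00190	G00191	G00192	G00193	G00194	G00195	G00196	G00197	G00198	G00199	G00200
urea_cycle	urea_cycle gene set	G00201	G00202	G00203	G00204	G00205	G00206	G00207	G00208	G00209	G00210	G00211	G00212	G00213	G00214	G00215	G00216	G00217	G00218	G00219	G00220
heme_metabolism	heme_metabolism gene set	G00221	G00222	G00223	G00224	G00225	G00226	G00227	G00228	G00229	G00230	G00231	G00232	G00233	G00234	G00235	G00236	G00237	G00238	G00239	G00240
cholesterol_biosynthesis	cholesterol_biosynthesis gene set	G00241	G00242	G00243	G00244	G00245	G00246	G00247	G00248	G00249	G00250	G00251	G00252	G00253	G00254	G00255	G00256	G00257	G00258	G00259	G00260
sphingolipid_metabolism	sphingolipid_metabolism gene set	G00261	G00262	G00263	G00264	G00265	G00266	G00267	G00268	G00269	G00270	G00271	G00272	G00273	G00274	G00275	G00276	G00277	G00278	G00279	G00280
glycogen_metabolism	glycogen_metabolism gene set	G00281	G00282	G00283	G00284	G00285	G00286	G00287	G00288	G00289	G00290	G00291	G00292	G00293	G00294	G00295	G00296	G00297	G00298	G00299	G00300
branched_chain_aa_catabolism	branched_chain_aa_catabolism gene set	G00301	G00302	G00303	G00304	G00305	G00306	G00307	G00308	G00309	G00310	G00311	G00312	G00313	G00314	G00315	G00316	G00317	G00318	G00319	G00320
beta_alanine_metabolism	beta_alanine_metabolism gene set	G00321	G00322	G00323	G00324	G00325	G00326	G00327	G00328	G00329	G00330	G00331	G00332	G00333	G00334	G00335	G00336	G00337	G00338	G00339	G00340
proline_metabolism	proline_metabolism gene set	G00341	G00342	G00343	G00344	G00345	G00346	G00347	G00348	G00349	G00350	G00351	G00352	G00353	G00354	G00355	G00356	G00357	G00358	G00359	G00360
nad_metabolism	nad_metabolism gene set	G00361	G00362	G00363	G00364	G00365	G00366	G00367	G00368	G00369	G00370	G00371	G00372	G00373	G00374	G00375	G00376	G00377	G00378	G00379	G00380
glutathione_metabolism	glutathione_metabolism gene set	G00381	G00382	G00383	G00384	G00385	G00386	G00387	G00388	G00389	G00390	G00391	G00392	G00393	G00394	G00395	G00396	G00397	G00398	G00399	G00400
arachidonic_acid_metabolism	arachidonic_acid_metabolism gene set	G00401	G00402	G00403	G00404	G00405	G00406	G00407	G00408	G00409	G00410	G00411	G00412	G00413	G00414	G00415	G00416	G00417	G00418	G00419	G00420
stress_markers	stress_markers gene set	G00421	G00422	G00423	G00424	G00425	G00426	G00427	G00428	G00429	G00430	G00431	G00432	G00433	G00434	G00435	G00436	G00437	G00438	G00439	G00440	G00441	G00442	G00443	G00444	G00445	G00446	G00447	G00448	G00449	G00450
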