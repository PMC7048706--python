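trait	Bloom	Lasso	Ridge	BLUP	GBM	RF	SVM
Cadmium chloride	0.780	0.779	0.445	0.556	0.797	0.786	0.565
Caffeine	0.197	0.203	0.171	0.229	0.250	0.236	0.234
Calcium chloride	0.198	0.255	0.240	0.268	0.261	0.205	0.261
Cisplatin	0.297	0.319	0.253	0.290	0.338	0.275	0.272
Cobalt chloride	0.431	0.455	0.431	0.457	0.460	0.398	0.448
Congo red	0.460	0.504	0.469	0.500	0.500	0.398	0.487
Copper	0.405	0.345	0.284	0.331	0.456	0.406	0.338
Cycloheximide	0.466	0.498	0.480	0.516	0.513	0.444	0.529
Diamide	0.417	0.479	0.468	0.498	0.460	0.318	0.486
E6_Berbamine	0.380	0.403	0.372	0.399	0.412	0.281	0.390
Ethanol	0.486	0.495	0.434	0.460	0.518	0.475	0.455
Formamide	0.310	0.238	0.179	0.232	0.350	0.298	0.240
Galactose	0.201	0.183	0.171	0.211	0.235	0.219	0.217
Hydrogen peroxide	0.362	0.377	0.308	0.365	0.385	0.355	0.399
Hydroquinone	0.135	0.201	0.173	0.225	0.212	0.191	0.188
Hydroxyurea	0.232	0.303	0.266	0.303	0.336	0.243	0.320
Indoleacetic acid	0.480	0.302	0.239	0.301	0.476	0.458	0.310
Lactate	0.523	0.568	0.522	0.552	0.561	0.510	0.557
Lactose	0.536	0.567	0.532	0.562	0.582	0.530	0.565
Lithium chloride	0.642	0.704	0.635	0.670	0.711	0.538	0.680
Magnesium chloride	0.278	0.229	0.196	0.250	0.266	0.255	0.267
Magnesium sulfate	0.519	0.369	0.326	0.360	0.492	0.434	0.378
Maltose	0.780	0.620	0.488	0.534	0.809	0.806	0.522
Mannose	0.230	0.202	0.162	0.210	0.255	0.234	0.215
Menadione	0.388	0.412	0.375	0.407	0.432	0.396	0.402
Neomycin	0.556	0.614	0.580	0.609	0.600	0.487	0.597
Paraquat	0.388	0.496	0.447	0.474	0.488	0.298	0.479
Raffinose	0.317	0.357	0.341	0.371	0.383	0.368	0.364
SDS	0.348	0.411	0.345	0.386	0.393	0.337	0.383
Sorbitol	0.424	0.369	0.296	0.333	0.379	0.383	0.318
Trehalose	0.489	0.500	0.463	0.487	0.515	0.472	0.477
Tunicamycin	0.492	0.605	0.586	0.618	0.618	0.385	0.634
x4-Hydroxybenzaldehyde	0.442	0.411	0.325	0.365	0.471	0.404	0.355
x4NQO	0.604	0.612	0.487	0.538	0.636	0.559	0.542
x5-Fluorocytosine	0.354	0.386	0.321	0.354	0.397	0.334	0.373
x5-Fluorouracil	0.503	0.552	0.512	0.545	0.536	0.454	0.546
x6-Azauracil	0.258	0.298	0.270	0.308	0.315	0.289	0.279
Xylose	0.475	0.468	0.431	0.465	0.516	0.484	0.460
YNB	0.508	0.541	0.481	0.519	0.543	0.411	0.525
YNB:ph3	0.151	0.18	0.144	0.195	0.194	0.153	0.166
YNB:ph8	0.295	0.345	0.315	0.356	0.354	0.267	0.334
YPD	0.533	0.546	0.480	0.515	0.556	0.469	0.524
YPD:15C	0.432	0.383	0.311	0.345	0.427	0.424	0.333
YPD:37C	0.711	0.653	0.576	0.606	0.691	0.686	0.603
YPD:4C	0.406	0.430	0.396	0.418	0.485	0.405	0.421
Zeocin	0.465	0.469	0.450	0.482	0.495	0.360	0.475
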