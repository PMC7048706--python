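trait	Lasso	Ridge	BLUP	GBM	RF	SVM
Culm diameter	0.142	0.191	0.190	0.145	0.163	0.182
Culm length	0.529	0.567	0.568	0.559	0.539	0.516
Culm number	0.205	0.232	0.233	0.188	0.222	0.247
Grain length	0.387	0.375	0.381	0.371	0.361	0.383
Grain width	0.474	0.508	0.511	0.466	0.435	0.500
Grain weight	0.309	0.379	0.380	0.327	0.350	0.387
Days to heading	0.677	0.693	0.698	0.669	0.657	0.636
Ligule length	0.351	0.382	0.376	0.372	0.367	0.390
Leaf length	0.335	0.406	0.405	0.407	0.388	0.414
Leaf width	0.371	0.409	0.406	0.388	0.384	0.416
Panicle length	0.352	0.399	0.399	0.383	0.388	0.416
Seedling height	0.188	0.224	0.226	0.184	0.188	0.202
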