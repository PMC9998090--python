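# elastic-score background calibration v1
# decoy_count=120
size	mean	sd
91.37	36.207424	36.838972
110.75	38.194122	39.117871
130.13	40.111673	41.271125
149.51	41.960078	43.317476
168.89	43.739335	45.271423
188.27	45.449445	47.144456
207.65	47.090409	48.945865
227.03	48.662225	50.683288
246.41	50.164895	52.363094
265.79	51.598417	53.990662
285.17	52.962793	55.570582
304.55	54.258021	57.106808
323.93	55.484103	58.602778
343.31	56.641037	60.061498
362.69	57.728825	61.485620
382.07	58.747466	62.877496
401.45	59.696959	64.239220
420.83	60.577306	65.572673
440.21	61.388506	66.879544
459.60	62.130558	68.161363
478.98	62.803464	69.419517
498.36	63.407223	70.655271
517.74	63.941835	71.869780
537.12	64.407300	73.064104
556.50	64.803618	74.239216
575.88	65.130789	75.396016
595.26	65.388813	76.535333
614.64	65.577690	77.657937
634.02	65.697420	78.764542
653.40	65.748003	79.855814
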