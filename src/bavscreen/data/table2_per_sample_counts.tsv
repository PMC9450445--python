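sample_id	total	cds	synonymous	missense	stopgain	stoploss	intronic	intergenic
BAV01	316629	25616	12459	12157	106	14	153569	110077
BAV02	316788	25060	12272	11774	117	13	155191	109148
BAV03	298898	25306	12353	11989	110	14	148645	98309
BAV04	281407	25049	12149	11959	125	12	142253	88484
BAV05	284138	25545	12527	12142	122	18	144372	87640
BAV06	288281	25062	12333	11950	103	16	142722	94138
BAV07	287824	25345	12360	12074	104	15	143073	93256
BAV08	319790	25367	12348	11965	109	13	157454	109216
BAV09	304337	25337	12383	11968	101	15	152857	97962
BAV10	306704	25673	12415	12272	98	14	152682	101295
BAV11	293218	25185	12234	11940	111	16	147598	93446
BAV12	298719	25430	12454	12058	109	19	146054	101176
BAV13	283332	25275	12376	11928	100	21	142473	89719
BAV14	272788	24997	12274	11881	106	12	138540	83700
BAV15	285330	25105	12237	11848	114	18	143174	91339
BAV16	322148	25097	12275	11886	108	12	157732	111678
BAV17	273457	25248	12176	12017	106	15	144827	76696
BAV18	292524	25540	12501	12071	108	16	147862	92285
BAV19	342694	25793	12422	12286	105	18	169225	117441
BAV20	330585	25388	12399	12017	104	12	174702	98433
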