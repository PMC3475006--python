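id	chromosome	start	end
cn_probe_01	14	38510003	38510062
cn_probe_02	14	38542068	38542127
cn_probe_03	14	38555801	38555860
cn_probe_04	14	38562310	38562358
cn_probe_05	14	38571564	38571623
cn_probe_06	14	38581765	38581824
cn_probe_07	14	38587626	38587685
cn_probe_08	14	38597108	38597167
cn_probe_09	14	38602277	38602335
cn_probe_10	14	38609230	38609289
cn_probe_11	14	38614898	38614957
cn_probe_12	14	38626492	38626551
cn_probe_13	14	38631536	38631595
cn_probe_14	14	38639169	38639225
cn_probe_15	14	38646487	38646546
cn_probe_16	14	38653819	38653878
cn_probe_17	14	38665516	38665575
cn_probe_18	14	38670657	38670716
cn_probe_19	14	38675867	38675926
cn_probe_20	14	38682480	38682539
cn_probe_21	14	38686855	38686914
cn_probe_22	14	38693139	38693198
cn_probe_23	14	38697285	38697344
cn_probe_24	14	38701438	38701497
cn_probe_25	14	38705250	38705309
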