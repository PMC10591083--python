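taxon	tier	current_size	mig_rcp26	mig_rcp85	nomig_rcp26	nomig_rcp85	reason
Brassica cretica Lam.	secondary	6769	0.03	-29.4	-33.9	-63.7
Brassica juncea (L.) Czern.	secondary						cultivated
Brassica rapa L.	secondary	250077	-9.6	-26.3	-26.2	-42.6
Erucastrum gallicum (Willd.) O. E. Schulz	secondary	103289	-29.5	-71.5	-40.6	-89.4
Brassica bourgeaui (Webb ex Christ) Kuntze	tertiary	246	-5.3	-9.3	-5.3	-9.3
Brassica carinata A. Braun	tertiary						Outside study area
Brassica deserti Danin & Hedge	tertiary						Only 3 GBIF records (2 after cleaning)
Brassica desnottesii Emb. & Maire	tertiary						Only 5 GBIF records (2 after cleaning)
Brassica dimorpha Coss. & Durieu	tertiary						Only 1 GBIF record (1 after cleaning)
Brassica elongata Ehrh.	tertiary	164251	-15.4	-39.6	-38.4	-72.3
Brassica fruticulosa Cirillo	tertiary	34699	4.8	-4.6	-27.7	-60.4
Brassica gravinae Ten.	tertiary	62615	-10.3	-28.3	-31.4	-69.6
Brassica hilarionis Post	tertiary						Only 5 GBIF records (3 after cleaning)
Brassica incana Ten.	tertiary	3167	80.2	244.7	-19.1	-49.3
Brassica insularis Moris	tertiary	9277	-66.0	-78.0	-66.5	-89.0
Brassica maurorum Durieu	tertiary	10732	-36.9	-62.3	-41.1	-68.3
Brassica montana Pourr.	tertiary	23133	40.8	23.4	-38.7	-76.0
Brassica nigra (L.) W. D. J. Koch	tertiary	159081	-0.1	-5.8	-9.0	-26.1
Brassica oleracea L.	tertiary						Cultivated
Brassica repanda (Willd.) DC.	tertiary	43996	-46.2	-87.6	-50.8	-89.7
Brassica souliei Batt. subsp. souliei Batt.	tertiary	32540	-45.7	-80.8	-54.1	-85.8
Brassica souliei Batt. subsp. amplexicaulis (Desf.) Greuter & Burdet	tertiary	5685	-77.7	-96.7	-82.1	-97.5
Brassica tournefortii Gouan	tertiary	73804	-1.8	22.3	-21.9	-23.3
Capsella bursa-pastoris (L.) Medik.	tertiary	280915	-7.6	-24.4	-16.1	-32.9
Crambe hispanica subsp. abyssinica (Hochst. ex R.E.Fr.) Prina	tertiary						Outside study area
Descurainia sophia (L.) Webb ex Prantl	tertiary	180923	-17.5	-44.0	-34.6	-66.3
Diplotaxis acris (Forsk.) Boiss.	tertiary	10445	56.8	133.2	-23.2	-15.5
Diplotaxis catholica (L.) DC.	tertiary	42412	-6.1	-24.3	-17.7	-47.0
Diplotaxis erucoides (L.) DC.	tertiary	68478	49.2	37.7	-12.8	-36.1
Diplotaxis harra (Forssk.) Boiss.	tertiary	47471	39.1	84.0	-7.1	-4.9
Diplotaxis muralis (L.) DC.	tertiary	132933	2.3	-9.7	-12.9	-35.4
Diplotaxis siifolia Kunze	tertiary	27283	-17.2	-41.3	-28.7	-52.9
Diplotaxis tenuifolia (L.) DC.	tertiary	127278	-1.7	-14.5	-16.5	-42.9
Diplotaxis viminea (L.) DC.	tertiary	77775	29.3	19.1	-9.6	-28.6
Enarthrocarpus lyratus (Forssk.) DC.	tertiary	2013	-13.3	-16.7	-51.1	-52.9
Eruca vesicaria (L.) Cav.	tertiary	133801	-1.8	-19.4	-16.8	-38.5
Erucastrum abyssinicum R. E. Fr.	tertiary						Outside study area
Hirschfeldia incana (L.) Lagr.-Foss.	tertiary	159233	9.4	-1.6	-8.1	-24.3
Moricandia arvensis (L.) DC.	tertiary	60456	8.6	17.9	-19.8	-41.8
Moricandia nitens (Viv.) E. A. Durand & Barratte	tertiary	25965	-6.6	10.2	-29.9	-29.0
Orychophragmus violaceus (L.) O.E. Schulz	tertiary						Outside study area
Physaria fendleri (A. Gray) OKane & Al-Shehbaz	tertiary						Outside study area
Raphanus raphanistrum L.	tertiary	255467	2.6	1.3	-16.1	-24.6
Raphanus sativus L.	tertiary						Cultivated
Rapistrum rugosum (L.) All.	tertiary	171637	4.2	-5.9	-8.3	-24.5
Rorippa indica (L.) Hiern	tertiary						Outside study area
Rorippa islandica (Oeder) Borb	tertiary	108211	-31.8	-72.5	-41.1	-85.0
Sinapis alba L.	tertiary	203160	2.3	-0.3	-9.9	-24.0
Sinapis arvensis L.	tertiary	299489	-8.8	-25.3	-19.6	-36.1
Sinapis pubescens L.	tertiary	38339	-9.1	9.3	-24.1	-49.3
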