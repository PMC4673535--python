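mirna	value	style
miR-6243	43187	plain
miR-5109	30926	plain
miR-2137	29793	plain
miR-6240	25457	bold
miR-5126	21891	plain
miR-3960	16884	plain
miR-2861	16171	plain
miR-711	13240	bold
miR-762	11201	plain
miR-6538	7735.3	plain
miR-328-5p	6137.8	plain
miR-149-3p	4842.1	plain
miR-326-5p	3921	plain
miR-6236	2569.2	bold
miR-5115	2450.3	plain
miR-5627-5p	2341.9	plain
miR-3473e	2248.7	plain
miR-3473b	2165.5	plain
miR-1892	2066.9	bold
miR-3072-5p	1982.1	plain
miR-3102-5p	1979.3	plain
miR-3077-5p	1893.9	plain
miR-1965	1840.2	plain
miR-744-5p	1734.5	plain
miR-6244	1730.4	plain
miR-211-3p	1670.2	plain
miR-5128	1531.3	plain
miR-215-5p	1364.4	plain
miR-5621-5p	1356.8	plain
miR-5130	1233.5	plain
miR-3473a	1144.9	plain
miR-3107-3p	1144.5	plain
miR-680	1117.6	plain
miR-204-3p	1102.8	bold
miR-3090-5p	1073.3	plain
miR-92b-5p	998.5	plain
miR-346-3p	987.4	plain
miR-128-2-5p	949.4	plain
miR-3104-5p	941.6	plain
miR-5132-5p	870.5	plain
miR-1224-5p	805.1	plain
miR-370-3p	652.1	bold
miR-5620-5p	635.7	bold
miR-5116	572.3	plain
miR-2136	548.1	plain
miR-709	545.1	plain
miR-6378	504.7	plain
miR-296-5p	496.5	plain
miR-92a-2-5p	492.2	plain
miR-365-1-5p	475.9	plain
miR-1893	457.8	plain
miR-671-5p	448.7	plain
miR-1894-3p	424.5	bold
miR-6394	402.9	bold
miR-6351	399.2	bold
miR-1249-5p	396.7	plain
miR-705	380.6	plain
miR-6391	379	plain
miR-5122	356.9	plain
miR-1964-5p	341.6	plain
miR-5099	335.9	plain
miR-5620-3p	312.5	bold
miR-5114	292.4	plain
miR-3474	290.1	plain
miR-6239	289.8	plain
miR-3572-5p	268.4	plain
miR-3067-3p	265.7	plain
miR-1895	263.8	plain
miR-714	252.3	plain
miR-486-3p	246.9	plain
miR-1934-3p	227.2	plain
miR-363-5p	219	plain
miR-31-5p	218.5	bold
miR-5622-3p	215	plain
miR-6370	215	plain
miR-1249-3p	214.7	plain
miR-1940	202.2	plain
miR-6392-3p	170.8	plain
miR-1198-5p	166.5	plain
miR-223-3p	166.1	plain
miR-185-3p	158.8	plain
miR-3087-5p	146.8	plain
miR-712-3p	143.4	plain
miR-615-5p	125.8	plain
miR-710	125.2	plain
miR-466f	112	plain
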