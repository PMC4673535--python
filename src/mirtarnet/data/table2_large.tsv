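mirna	value	style
miR-3473e	3.499	plain
miR-5099	3.481	plain
miR-223-3p	3.415	bold
miR-5128	3.339	bold
miR-3473b	3.048	bold
miR-680	2.828	bold
miR-3474	2.484	plain
miR-6244	2.469	plain
miR-744-5p	2.443	plain
miR-762	2.33	plain
miR-328-5p	2.329	plain
miR-6243	2.304	plain
miR-6239	2.285	plain
miR-6406	2.153	plain
miR-6349	2.112	plain
miR-5126	2.087	plain
miR-3077-5p	2.009	plain
miR-709	2.007	plain
miR-1224-5p	1.909	bold
miR-1249-5p	1.907	plain
miR-705	1.882	plain
miR-770-3p	1.682	plain
miR-3960	1.67	plain
miR-6240	1.64	plain
miR-5130	1.576	bold
miR-714	1.562	plain
miR-690	1.561	bold
miR-326-5p	1.508	plain
miR-149-3p	1.499	plain
miR-5116	1.494	bold
miR-3090-5p	1.485	plain
miR-5621-5p	1.477	plain
miR-191-5p	1.47	plain
miR-3104-5p	1.468	plain
miR-365-1-5p	1.461	plain
miR-6538	1.46	plain
miR-92a-2-5p	1.45	plain
miR-2137	1.449	plain
miR-1965	1.443	plain
miR-2861	1.414	plain
miR-671-5p	1.364	bold
miR-378a-3p	1.32	plain
miR-378c	1.268	plain
miR-3473a	1.245	bold
miR-378d	1.214	plain
miR-107-3p	1.165	plain
miR-3072-5p	1.141	plain
miR-5109	1.13	plain
miR-1893	1.129	plain
miR-17-5p	1.066	plain
miR-5132-5p	1.022	plain
miR-125a-3p	-2.568	plain
miR-1902	-2.55	plain
miR-1983	-2.126	plain
miR-3963	-1.774	bold
miR-6412	-1.683	plain
let-7g-5p	-1.666	bold
miR-141-3p	-1.657	bold
miR-375-5p	-1.462	plain
let-7f-5p	-1.453	bold
miR-29b-3p	-1.412	plain
miR-3968	-1.304	bold
let-7c-5p	-1.14	bold
let-7b-5p	-1.062	bold
miR-21a-5p	-1.051	bold
miR-3072-3p	-1.01	plain
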