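mirna	value	style
miR-5126	25994	italic
miR-690	18875	plain
miR-5105	15012	plain
miR-3473e	5846.9	italic
miR-3473b	4691.6	italic
miR-5128	2937.8	italic
miR-200a-3p	2646.2	bold
miR-744-5p	2513.9	italic
miR-3077-5p	2129.2	italic
miR-5621-5p	1518.1	italic
miR-5099	1467.4	bold
miR-378a-3p	1040.4	bold
miR-200b-3p	1003.5	bold
miR-709	977.1	italic
miR-378d	914.5	bold
miR-23a-3p	911.4	bold
miR-378c	899.6	bold
miR-23b-3p	862.8	bold
miR-29a-3p	752.4	bold
miR-378b	685.3	bold
miR-26a-5p	668	bold
miR-10a-5p	663.6	bold
miR-107-3p	586.9	plain
miR-191-5p	562.9	plain
miR-3474	508.4	italic
miR-103-3p	489.8	bold
miR-770-3p	419.4	plain
miR-1249-5p	406.4	italic
miR-10b-5p	380.2	bold
miR-30d-5p	343.4	bold
miR-27a-3p	338.8	bold
miR-5112	305.5	plain
miR-22-3p	301	bold
miR-6349	251.7	plain
miR-27b-3p	219.6	bold
miR-141-3p	180.8	bold
miR-712-5p	167.3	plain
miR-6406	139.4	plain
miR-205-5p	131.4	plain
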