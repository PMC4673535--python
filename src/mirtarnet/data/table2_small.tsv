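mirna	value	style
miR-223-3p	1.327	bold
miR-345-3p	-4.002	plain
miR-346-3p	-1.796	plain
miR-1893	-1.679	plain
miR-141-3p	-1.667	plain
miR-1902	-1.652	plain
miR-1934-3p	-1.626	plain
miR-365-1-5p	-1.62	plain
miR-375-5p	-1.53	plain
miR-5622-3p	-1.511	plain
miR-5122	-1.5	plain
miR-1964-5p	-1.429	plain
miR-3960	-1.422	plain
miR-494-3p	-1.412	plain
miR-5112	-1.384	plain
miR-3102-5p.2-5p	-1.317	plain
miR-6391	-1.186	plain
miR-204-3p	-1.185	plain
miR-1983	-1.161	plain
miR-671-5p	-1.122	plain
miR-5105	-1.12	plain
miR-3963	-1.108	plain
miR-3077-5p	-1.073	plain
miR-1249-5p	-1.07	plain
miR-5130	-1.049	plain
miR-5620-5p	-1.042	plain
miR-6366	-1.036	plain
miR-6378	-1.025	plain
miR-211-3p	-1.02	plain
miR-1965	-1.006	plain
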