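mirna	value	style
miR-6240	18940	bold
miR-711	8050.7	bold
miR-6236	2438.7	bold
miR-215-5p	2219.9	plain
miR-1892	1897.3	bold
miR-204-3p	485	bold
miR-370-3p	419.7	bold
miR-5620-5p	308.7	bold
miR-1894-3p	300.1	bold
miR-6394	298.1	bold
miR-5620-3p	245.5	bold
miR-31-5p	241.6	bold
miR-6351	220.9	bold
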