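mirna	value	style
miR-6412	5600.3	plain
miR-200a-3p	2073.9	bold
miR-200b-3p	1524.1	bold
miR-21a-5p	1137.5	plain
miR-23b-3p	853.9	bold
miR-23a-3p	657.2	bold
miR-125a-3p	630.9	plain
let-7c-5p	614.6	plain
miR-26a-5p	608.4	bold
let-7a-5p	577.9	plain
miR-141-3p	570.2	bold
let-7f-5p	557.1	plain
miR-29a-3p	540.1	bold
miR-30c-5p	537.5	plain
let-7d-5p	535.2	plain
miR-200c-3p	529.1	plain
let-7b-5p	521.1	plain
miR-429-3p	496.4	plain
miR-27b-3p	426.9	bold
miR-378a-3p	416.6	bold
miR-378d	394.1	bold
miR-30b-5p	391.8	plain
miR-27a-3p	390.9	bold
miR-378c	373.5	bold
miR-10a-5p	369.4	bold
miR-378b	362.6	bold
let-7g-5p	358	plain
miR-103-3p	343.6	bold
miR-30d-5p	258.1	bold
miR-10b-5p	255.3	bold
miR-29b-3p	231	plain
miR-22-3p	225.9	bold
miR-30a-5p	175	plain
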