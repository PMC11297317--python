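label	proteins	normal_images	tumor_images
Cytoplasm	72	179	537
Endoplasmic reticulum	12	30	105
Golgi apparatus	20	50	145
Mitochondria	46	108	359
Plasma membrane	19	47	126
Nuclear	170	396	1342
Vesicles	24	59	187
Total	332	792	2583
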