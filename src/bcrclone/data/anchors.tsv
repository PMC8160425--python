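segment	segment_type	anchor
IGHV1-2*01	V	288
IGHV3-23*01	V	288
IGHV4-34*01	V	288
IGHV5-51*01	V	288
IGHV6-1*01	V	288
IGHJ4*01	J	12
IGHJ5*01	J	12
IGHJ6*01	J	12
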