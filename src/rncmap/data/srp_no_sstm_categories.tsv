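category	count
Unknown	63
Nucleus	61
Mitochondrion	31
Ribosome	10
Endoplasmic reticulum	9
Endomembrane system	9
Plasma membrane	3
Vacuole	3
Golgi apparatus	2
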