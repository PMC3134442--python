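category	count
Unknown	179
Mitochondrion	150
Nucleus	69
Plasma membrane	40
Endoplasmic reticulum	36
Endomembrane system	27
Vacuole	24
Cell wall	22
Golgi apparatus	13
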