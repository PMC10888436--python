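# SYNTHETIC placeholder split-intein pair.
# The IntC/IntN fragments used for real SIML constructs (e.g. the Npu DnaE
# split intein) are configuration inputs: replace this file with a YAML
# carrying the curated protein sequences.  The placeholders below are short
# synthetic sequences used for structural tests only.
name: synthetic_placeholder_intein
c_first: true
int_c: GDSHETKLVNAEC
int_n: GTSNAELKRLGIDPETNHKVFSAEG
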