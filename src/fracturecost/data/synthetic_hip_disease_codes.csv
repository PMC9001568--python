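code,code_class
HIPFX-NECK-FRAG-A,neck_fragility
HIPFX-NECK-FRAG-B,neck_fragility
HIPFX-EXTRACAP-FRAG-A,extracapsular_fragility
HIPFX-EXTRACAP-FRAG-B,extracapsular_fragility
HIPFX-OPEN-A,hip_other
HIPFX-STRESS-A,hip_other
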