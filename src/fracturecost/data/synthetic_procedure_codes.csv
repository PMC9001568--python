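code,procedure_class
PROC-THR-A,thr
PROC-BHA-A,bipolar
PROC-ORIF-A,orif
PROC-CONS-A,conservative
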