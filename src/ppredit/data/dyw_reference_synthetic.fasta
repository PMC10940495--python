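>dyw_reference_synthetic constructed canonical DYW-domain stand-in
GDTSRVMAKLVHAEIGKRSWNPCSFCGALNTEVRSGSETLVMCGQWSAKYNPRVDYW
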