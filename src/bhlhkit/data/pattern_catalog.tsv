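label	slots
I	10:0,27:0,50:0
II	10:0,27:0
III	27:0,50:0
IV	10:0
V	27:0
VI	50:0
VII	20:1
VIII	40:1
IX	20:1,40:1
X
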