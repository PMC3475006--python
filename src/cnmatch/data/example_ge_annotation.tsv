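id	chromosome	start	end
A_23_P140170	14	38570874	38642188
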