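name,formula
bezafibrate,C19H20ClNO4
oleic acid,C18H34O2
palmitic acid,C16H32O2
stearic acid,C18H36O2
water,H2O
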