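standard,slope,intercept,r_squared,wavelength_nm
rutin,10.655,-0.0076,0.99869,510
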