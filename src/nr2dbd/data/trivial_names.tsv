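trivial_name	nomenclature_name
Sm2DBD-NRgamma	Sm2DBD-NRA1
Sm2DBD-NRalpha	Sm2DBD-NRA2
Sm2DBD-NRbeta	Sm2DBD-NRA3
Eg2DBDalpha1	Eg2DBD-NRA2
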