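compound,eps_homo,eps_lumo,gap_printed
TNT,-9.0,-3.5,5.5
DN6,-8.5,-3.0,5.6
DN4,-8.3,-2.8,5.6
4AD,-7.0,-2.6,4.4
2AD,-7.1,-2.8,4.4
TNB,-9.6,-3.7,5.9
NBZ,-8.1,-2.5,5.7
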