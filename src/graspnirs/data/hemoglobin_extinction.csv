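# Molar extinction coefficients of human hemoglobin, epsilon in cm^-1 / (mol/L),
# base-10 convention. Compiled literature values (Gratzer / Kollias tabulation as
# distributed by S. Prahl, Oregon Medical Laser Center). Converted to base-e by
# the loader (multiplied by ln 10) because this package defines optical density
# with the natural logarithm.
# wavelength_nm,eps_hbo2,eps_hbr
690,276.0,2051.96
730,390.0,1102.20
760,586.0,1548.52
780,710.0,1075.44
808,844.0,723.52
830,974.0,693.04
850,1058.0,691.32
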