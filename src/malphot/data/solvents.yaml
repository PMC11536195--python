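# Solvent -> static relative permittivity (dielectric constant, dimensionless).
# Values at 20-25 degC.  Hexane, diethyl ether, chloroform, methanol and
# acetonitrile are the values used throughout the wavelength model; the
# remainder are standard handbook values (CRC Handbook, 20-25 degC).
hexane: 1.88
cyclohexane: 2.02
dioxane: 2.25
toluene: 2.38
diethyl ether: 4.33
chloroform: 4.88
ethyl acetate: 6.02
tetrahydrofuran: 7.58
thf: 7.58
dichloromethane: 8.93
ethanol: 24.5
methanol: 32.7
dmf: 36.7
dimethylformamide: 36.7
acetonitrile: 37.5
dmso: 46.7
dimethyl sulfoxide: 46.7
water: 80.1
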