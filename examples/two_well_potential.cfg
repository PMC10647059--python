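# Two-well torsional potential: well-center free energies 1.0 kcal/mol apart.
# well = chi1_center, chi2_center, kappa, depth   (or 5 values: kappa per axis)
temperature = 300
well = -52.5, -7.5, 6, 3.0
well = 127.5, 172.5, 6, 2.0
frames = 25000
step = 60
seed = 1
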