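# Dopamine-depleted parameter set: strengthened GPe->STN inhibition and
# STN->PPN excitation, weakened GPe self-inhibition and PPN->STN feedback.
# The STN-GPe loop settles onto a ~22 Hz beta-band limit cycle.
stn: {H: 20.0, x: 0.006, r: 300.0, y: 0.1}
gpe: {H: 20.0, x: 0.014, r: 400.0, y: 0.1}
ppn: {H: 20.0, x: 0.005, r: 200.0, y: 0.1}
coupling: {lambda1: 5.0, lambda2: 20.0, lambda3: 2.0, lambda4: 13.0, lambda5: 1.0}
inputs:
  cor_mean: 27.0
  cor_sd: 0.1
  str_mean: 2.0
  str_sd: 0.1
  gpi_mean: 20.0
  gpi_sd: 0.1
simulation: {T: 3.0, dt: 1.0e-4, seed: 0}
scheme: null
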