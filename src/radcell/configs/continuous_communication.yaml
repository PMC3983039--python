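# Continuous exposure, communication model: three decline phases with a
# quasi-stationary plateau before the final decline.
model:
  variant: communication
  alpha: 0.1
  p: 0.05
  c: 1.0
  eta: 0.01
  beta0: 10.0
  beta1: 0.0
initial: [100, 0, 0, 0]
t_end: 1.0e+6
n_points: 800
grid: log
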