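# Continuous exposure, memory model: two decline phases, all cells altered.
model:
  variant: memory
  alpha: 0.1
  p: 0.05
  c: 1.0
  eta: 0.01
initial: [100, 0, 0, 0]
t_end: 1.0e+5
n_points: 600
grid: log
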