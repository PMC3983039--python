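# Priming + challenge, memory model, dose affecting only the hit rate:
# priming can never reduce the number of altered cells.
model:
  variant: memory
  alpha: 0.1
  p: 0.05
  c: 1.0
  eta: 0.01
initial: [100, 0, 0, 0]
schedule:
  default_p: 0.05
  segments:
    - {t_start: 0, t_end: 10, alpha: 0.1, p: 0.05}
    - {t_start: 20, t_end: 25, alpha: 100.0, p: 0.05}
t_end: 200
n_points: 401
grid: linear
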