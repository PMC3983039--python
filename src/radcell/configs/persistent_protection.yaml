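# Communication between adapted and healthy cells (beta1 > 0): after the
# priming beam stops, the protected pool equilibrates at x = eta/beta1
# instead of waning.
model:
  variant: communication
  alpha: 0.1
  p: 0.05
  c: 1.0
  eta: 0.01
  beta0: 10.0
  beta1: 1.0
initial: [100, 0, 0, 0]
schedule:
  default_p: 0.05
  segments:
    - {t_start: 0, t_end: 10, alpha: 0.1, p: 0.05}
t_end: 2000
n_points: 600
grid: linear
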