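# radcell

Compartment-model simulation and inference of cellular responses to
ionizing radiation.

`radcell` is aimed at radiobiology modellers who want a tested, scriptable
implementation of the minimal population dynamics behind three low-dose
phenomena: **radioadaptive responses** (a low priming dose protecting
against a later challenge), **low-dose hyper-radiosensitivity (HRS)** and
**increased radioresistance (IRR)** in clonogenic survival curves, and the
**quasi-stationary survival** of communicating cell populations under
continuous exposure.

## The model

A non-dividing population of `k` cells is split into healthy susceptible
cells `x`, hit cells undergoing repair `y`, adapted (protected) cells `w`,
and permanently altered cells `z` (death, mutation or aberration — the
endpoint is not distinguished). With hit rate `α`, repair-resolution rate
`c`, failure probability `p`, protection-loss rate `η` and mass-action
communication rates `β₀` (repairing → healthy) and `β₁` (adapted →
healthy), the unified dynamics are

```
dx/dt = −αx − (β₀y + β₁w)x + ηw + (1−m)(1−p)cy
dy/dt =  αx − cy
dw/dt =  m(1−p)cy + (β₀y + β₁w)x − ηw
dz/dt =  pcy
```

where the switch `m` selects the **memory model** (`m=1`, `β=0`: a
successfully repaired cell is itself protected for a mean duration `1/η`)
or the **communication model** (`m=0`: repaired cells become susceptible
again and protection spreads only by cell-to-cell signalling). The total
`x+y+w+z` is conserved; under sustained exposure the only equilibrium is
the fully altered state `z = k`.

Dose–response curves read the surviving fraction `S/k = (x+y+w)/k` at the
end of an exposure, with a dose-dependent kill probability `p(d)` — linear
`p₀ + p₁d` or saturating `p₁d/(d+p₀)` — delivered either at fixed duration
(dose sets the rate `α`) or at fixed rate (dose sets the exposure time).
The fitting module estimates `(α, η, p₀, p₁)` from dose–survival tables by
multi-start bounded least squares in log-survival space, with `c` fixed
at 1.

## Worked example

Simulate continuous low-dose exposure in both model variants and compare
their decline structure:

```python
import radcell as rc

mem = rc.memory_model(alpha=0.1, p=0.05, c=1.0, eta=0.01)
com = rc.communication_model(alpha=0.1, p=0.05, c=1.0, eta=0.01, beta0=10.0)

traj_m, s_m = rc.continuous_exposure(mem, t_end=1e5)
traj_c, s_c = rc.continuous_exposure(com, t_end=1e6, n_points=800)
print(f"memory:        z(1e5) = {s_m['final_z']:.1f}, "
      f"{s_m['n_phases']} decline phases, late rate {s_m['late_rate']:.2e}")
print(f"communication: z(1e6) = {s_c['final_z']:.1f}, "
      f"{s_c['n_phases']} decline phases")
print(rc.qss_metrics(traj_c))
```

prints

```
memory:        z(1e5) = 100.0, 2 decline phases, late rate 4.52e-04
communication: z(1e6) = 100.0, 3 decline phases
QssMetrics(present=True, t_start=0.726722244226973, t_end=35255.41046469512, duration=35254.68374245089, mid_rate=5.061316289444093e-05, final_rate=np.float64(0.004075369941406217))
```

Both populations end fully altered (`z = k = 100`), but the communication
model interposes a quasi-stationary plateau of ≈3.5×10⁴ time units during
which the unaltered population declines two orders of magnitude more slowly
than in its final phase — communicated protection keeps the population
practically stable long after the memory-model population is gone.

The same experiments are available from the shell:

```
radcell simulate --config src/radcell/configs/continuous_memory.yaml --out traj.csv
radcell phases --trajectory traj.csv --out phases.csv
radcell dose-response --out curve.csv         # HRS/IRR survival curve
radcell adapt --ratio-curve --out ratio.csv   # priming-ratio threshold scan
```

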