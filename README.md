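# ubcsim

Conductance-based models of cerebellar **unipolar brush cell (UBC)**
feed-forward circuits.

UBCs are excitatory interneurons of the cerebellar granule layer that
transform a brief mossy-fiber input into a prolonged response: **ON**
UBCs fire a long burst (an AMPA-receptor rebound current that far
outlasts the stimulus), while spontaneously active **OFF** UBCs pause
(an mGluR2 → G-protein → GIRK potassium current).  Because UBCs also
synapse onto one another, two-cell chains can extend, invert and delay
spiking signals.  `ubcsim` is for computational neuroscientists who
want to simulate and quantify these transformations: it implements the
single-compartment ON/OFF UBC neurons, glutamate volume-transmission
from point-source release (the porous-medium kernel
`C = N/(α(4πD*t)^{3/2})·exp(−r²/4D*t)` with `D* = D/λ²`), an AMPA
Markov scheme with desensitization and a slow rebound open state, the
mGluR2 cascade `dR/dt = k1·T²(1−R) − k2·R`, `dG/dt = k3·R − k4·G`,
`I = g·G⁴/(G⁴+K_d)·(V+90)`, and the burst/pause/delay metrics computed
on the resulting spike trains.

## Worked example

Drive a chain of two ON UBCs with three presynaptic spikes spanning
19.6 ms and measure how each cell stretches the signal:

```python
import ubcsim as u
from ubcsim.metrics import burst_duration

stim = u.make_presyn_train(3, 9.8, 1000.0, window=(0.0, 5500.0))
res = u.run_circuit(u.motif_circuit("on-on"), stim,
                    duration=5500.0, settle_ms=1500.0)
for node in ("on1", "on2"):
    dur, n = burst_duration(res.spikes[node], 1000.0)
    print(f"{node}: {n} spikes, {dur:.1f} ms")
```

```
on1: 12 spikes, 401.9 ms
on2: 37 spikes, 1052.6 ms
```

A 19.6 ms input becomes a ~0.4 s burst in the first ON UBC and a ~1.1 s
burst in the second — a ~50-fold extension of the signal.  The same
machinery is available from the shell:

```bash
ubcsim run --preset on-on-3spike          # metrics as JSON
ubcsim sweep --motif on-off --spikes 1:10 # tidy CSV per input count
ubcsim calibrate --out calibrated         # staged calibration workflow
ubcsim validate                           # fast analytic self-checks
```

Motif presets: `on`, `off`, `on-on`, `on-off`, `off-on`, `off-off`
(presynaptic cell first; the receptor on each synapse follows the
postsynaptic subtype, AMPA for ON and mGluR2 for OFF).  All model
parameters round-trip through YAML configs (`ubcsim.save_config` /
`load_config`), with channel keys named after the conductance-table
rows (`gNa`, `gK`, `gH`, `gpas`, `gKslow`).

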