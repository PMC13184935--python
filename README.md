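# washkin

Washout kinetics of membrane-partitioned CFTR potentiators.

Lipophilic potentiators of the CFTR chloride channel bind at a
protein–membrane interface site. When the bath is perfused with drug-free
solution ("washout"), the potentiated current decays as drug leaves the
channel — but a ligand that dissociates into the membrane can either escape
to water or rebind before escaping, so the functional residence time is set
by membrane partitioning as much as by protein affinity. `washkin`
implements this three-state kinetic picture and everything needed to
exercise it on synthetic patch-clamp data:

* **kinetics** — the water/membrane/protein-bound compartment model with the
  water pool clamped (drug application or washout). Two limiting regimes:
  fast membrane exit (`k_lw ≫ k_a[P_t]`), where the current decays
  exponentially with `T = 1/k_-a`; and fast rebinding (`k_a[P_t] ≫ k_lw`),
  where the (non-exponential) decay is well approximated by one exponential
  with `T ≈ [P_t]/(1.53·K_d·k_lw)`, `K_d = k_-a/k_a`. The 1.53 constant is
  reproducible numerically (`single_exp_prefactor_numeric`).
* **traces** — synthetic inside-out patch recordings (baseline → drug →
  washout, 500 Hz, additive Gaussian noise) with packaged analog presets
  (ABBV-974 and its isobutyl/hexyl/decyl/NBD conjugates) carrying measured
  fold-potentiation values and chain-length-ordered membrane exit rates.
* **fitting** — plateau-ratio fold-potentiation estimates, single-exponential
  washout fits with free offset, replicate summaries (mean ± sample SD, n).
* **lipophilicity** — the scaling law `k_lw1/k_lw2 = 10^(−logP1/2)/10^(−logP2/2)`
  linking R-group hydrophobicity to membrane exit, the one-parameter
  prediction `rate = A·10^(−logP/2)`, its ratio-loss fit and r² on mean rates.
* **weighted_ensemble** — a desk-scale weighted-ensemble sampler (fixed bins,
  4 walkers per bin, split/merge resampling, recycling-flux rate estimator)
  on a 1-D Brownian toy landscape, validated against brute-force
  first-passage simulation.
* **pipeline / cli** — a seeded end-to-end run from trace generation to the
  logP fit; console script `washkin` with subcommands `simulate`, `fit`,
  `link`, `we-demo`, `pipeline`, `config`.

## Worked example

```python
import numpy as np
from washkin import (PRESETS, default_protocol, generate_trace,
                     estimate_potentiation, fit_washout, scenario2_tau)

preset = PRESETS["CFTRi-C3"]
trace = generate_trace(preset, default_protocol(preset), noise_sd=0.05, seed=1)
print(round(estimate_potentiation(trace), 3))   # 2.938
print(round(fit_washout(trace).tau, 2))          # 15.43  (s)
print(round(scenario2_tau(preset.kinetics), 2))  # 6.54   (s)
```

The potentiation estimate recovers the preset fold (2.94) from the noisy
trace. The fitted washout time constant (15.4 s) exceeds the ideal
fast-rebinding value (6.5 s) because the loaded membrane acts as a drug
reservoir that delays the decay — the same reason long-chain analogs wash
out slowly. Across the packaged presets the fitted time constants order
strictly C3 < C6 < C10.

Command-line equivalent:

```sh
washkin simulate --analog CFTRi-C3 --seed 1 --noise 0.05 --out trace.csv
washkin fit --trace trace.csv --out fit.json
washkin pipeline --outdir results/pipeline
```

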