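# b2arsim

Deterministic kinetic simulation of GRK-mediated β2 adrenergic receptor
(β2AR) regulation: agonist-dependent GRK phosphorylation, arrestin binding,
clathrin-mediated internalization, recycling, dephosphorylation,
desensitization and resensitization, in one unified reaction network.

The package is aimed at receptor pharmacologists and systems biologists who
want to simulate how a GPCR's signaling capacity evolves under arbitrary
stimulation schedules — sustained agonist, washout, competitive antagonist
block, or rapid pulsatile delivery — and to probe which steps of the
trafficking cycle control each biochemical readout.

## The model

A single pool of receptor (total normalized to 1) is distributed over ten
species: naive surface receptor R_s, the agonist-bound active complex
R\*L_s, GRK-phosphorylated surface forms with and without agonist and/or
arrestin (R_g\*L_s, ArrR_g\*L_s, ArrR_gs, R_gs), internalized forms
(ArrR_gi, R_gi, R_i) and a degraded sink. All 16 reactions are
(pseudo-)first order — GRK and arrestin are in large cellular excess and
enter only through rate constants — so within any constant ligand
environment the dynamics are a linear system dy/dt = A·y whose exact
solution is a matrix exponential. The simulator integrates the mass-action
equations with a stiff-capable stepper and verifies itself against the
independent expm-based solution.

Agonist concentration enters through equilibrium occupancy
[R\*] = [L]/([L] + K_d), and the GRK phosphorylation rate is
k_2f = α·[R\*]·base, where α is the agonist's coupling efficiency relative
to epinephrine (1 for full agonists, down to 0.03 for ephedrine). A
competitive antagonist attenuates the agonist association rates 100,000-fold
while leaving dissociation untouched. Model variants A–F toggle plasma
membrane dephosphorylation (k2b, k7f), endosomal dephosphorylation (k10f)
and phospho-receptor recycling (k13f) to compare trafficking topologies.

Derived readouts mirror the standard assays: total GRK-phosphorylated
receptor (phosphosite antibody), surface receptor (hydrophilic antagonist
binding), internalized receptor, and "active" receptor
R_s + R\*L_s + 0.7·(R_g\*L_s + R_gs) (adenylyl cyclase stimulation, with
phosphorylated surface receptor retaining 70 % activity and arrestin-bound
or internalized receptor fully uncoupled).

## Worked example

```python
import numpy as np
from b2arsim import (
    RateSet, naive_state, build_standard_protocol, run_protocol,
    series, normalize, run_pulse_train, PulseTrainSpec, memory_index,
)

# GRK-site dephosphorylation: 5 min 1 uM isoproterenol, then propranolol
protocol = build_standard_protocol("dephosphorylation", "isoproterenol", 1000.0)
traj = run_protocol(naive_state(), protocol, RateSet())
phospho = normalize(series(traj, "phosphorylated"), "percent_of_switch", switch_time=5.0)
for t in (5, 10, 20, 35):
    i = np.argmin(np.abs(phospho.times - t))
    print(f"phosphorylation at {t:>2d} min: {phospho.values[i]:6.1f} % of switch")

# latent memory under a rapid train of 1 uM isoproterenol pulses
result = run_pulse_train(PulseTrainSpec(n_pulses=3))
print(result.metrics.round(2).to_string(index=False))
print(f"memory index (pulse 2 - pulse 1): {memory_index(result):.1f} points")
```

prints

```
phosphorylation at  5 min:  100.0 % of switch
phosphorylation at 10 min:   84.4 % of switch
phosphorylation at 20 min:   58.6 % of switch
phosphorylation at 35 min:   34.3 % of switch
 pulse  desensitization_extent  peak_phospho_pct  internalized_end_pct
     1                   20.67             23.58                  0.99
     2                   37.39             41.14                  3.90
     3                   50.04             54.19                  7.60
memory index (pulse 2 - pulse 1): 16.7 points
```

The first block shows phosphorylation decaying with a roughly 18-minute
half-life once agonist rebinding is blocked. The second shows the latent
"cellular memory" of pulsatile stimulation: each 0.5-min pulse desensitizes
more deeply than the last (20.7 → 37.4 → 50.0 % loss of activity) because
slow surface dephosphorylation lets phosphorylated receptor accumulate
between pulses even though arrestin dissociates, and activity apparently
recovers, within seconds of each washout.

A command-line interface wraps the same machinery:

```sh
b2arsim simulate -c config.yaml -o out/      # trajectory + readout CSVs
b2arsim scan -c config.yaml --mode sensitivity
b2arsim export-sbml -c config.yaml -o model.xml
b2arsim list-agonists
b2arsim list-variants
```

where `config.yaml` names an experiment (or an explicit segment list), an
agonist and concentration, an optional model variant, and optional rate
overrides keyed by the canonical k-names (`k3f`, `k8f`, ...).

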