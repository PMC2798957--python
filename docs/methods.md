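# Methods

## Model structure

The simulator implements a closed first-order reaction network for a single
conserved pool of β2 adrenergic receptor. Ten species are tracked as
fractions of total receptor (R_total = 1): six on the plasma membrane
(R_s, R\*L_s, R_g\*L_s, ArrR_g\*L_s, ArrR_gs, R_gs), three internalized
(ArrR_gi, R_gi, R_i) and one degraded sink. The 16 reactions (23 directed
edges) cover agonist binding and dissociation, GRK phosphorylation and
dephosphorylation on the membrane and in endosomes, arrestin binding and
dissociation from agonist-bound and agonist-free complexes,
arrestin-dependent and basal internalization, recycling of phosphorylated
and dephosphorylated receptor, and slow degradation of any internalized
species.

Key structural assumptions:

- **Two-state activation.** Agonist binding produces the active complex
  directly; constitutive (agonist-independent) activity is ignored, since
  basal GRK phosphorylation is negligible.
- **Single phosphorylation event.** One GRK-phosphorylated state stands in
  for the multi-site reality; intermediate phospho-states matter on much
  shorter timescales than the 0.5–30 min trafficking events modeled here.
- **Pseudo-first-order GRK and arrestin.** Both proteins are in large
  excess over receptor (≈100-fold for GRKs in the reference cell system),
  so their concentrations are folded into rate constants and no arrestin
  conservation is modeled.
- **Ligand release on internalization** (reaction ArrR_g\*L_s → ArrR_gi)
  and equal slow degradation (0.004/min, t½ ≈ 3 h) from all three
  internalized species. De novo receptor synthesis is not modeled.
- **Ambiguous basal-internalization edge.** Three basal internalization
  constants exist (k11b, k12f, k13b). k11b internalizes R_s and k13b
  internalizes R_gs; the remaining k12f is assigned to ArrR_gs → ArrR_gi,
  the third surface species that needs an internalization route.

## Parameters

All rates in /min, concentrations in nM. Defaults:

| process | constants | value |
|---|---|---|
| agonist association | k1f = k4b = k5b | 500 (0.005 under antagonist) |
| agonist dissociation | k1b = k4f = k5f | 4 |
| GRK phosphorylation | k2f | α·occupancy·base (resolved per environment) |
| dephosphorylation | k2b = k7f = k10f | 0.036 (phospho t½ = 18 min) |
| arrestin on (agonist-bound) | k3f | 27 |
| arrestin off (agonist-bound) | k3b | 4 |
| arrestin off (agonist-free) | k6f = k9f | 11 |
| internalization | k8f | 0.22 |
| basal internalization | k11b = k12f = k13b | 0.0085 |
| recycling | k11f = k13f | 0.09 |
| degradation | k14f = k15f = k16f | 0.004 |

The association rates are deliberately fast-but-finite: binding must not be
rate-limiting for downstream events, and concentration dependence enters
solely through occupancy [L]/([L]+K_d) inside k2f. The base phosphorylation
rate is 1.4/min for the epinephrine family (K_d 450 nM) and 0.7/min for
isoproterenol (K_d 283 nM), both inside the experimentally measured
0.7–1.4/min initial-rate band at saturating agonist. Partial agonists carry
coupling efficiencies α relative to epinephrine (fenoterol 0.66 …
ephedrine 0.03) and, in the shipped library, inherit epinephrine's K_d and
base rate so that α (plus, for salmeterol, a 10-fold slower arrestin
on-rate and 10-fold faster off-rate) carries the entire between-ligand
difference at the saturating 10 µM panel concentration. A competitive
antagonist divides the three association constants by exactly 10^5,
leaving dissociation unchanged. The arrestin dissociation rate from the
ligand-free surface complex is 11/min by default and configurable.

## Protocols and washout semantics

A protocol is an ordered list of constant-environment segments. Plain
washout sets association rates to zero and lets bound agonist leave at
4/min; it is used for the recycling experiment. Antagonist segments use the
10^5 attenuation and are used for dephosphorylation and resensitization.
Pulse trains additionally support an *instantaneous dissociation* entry
action — a mass-preserving permutation moving R\*L_s → R_s,
R_g\*L_s → R_gs, ArrR_g\*L_s → ArrR_gs at the segment boundary — the
idealization appropriate for sub-minute washouts. The two washout modes
converge to the same state when bound ligand has fully dissociated and
downstream reactions are frozen (a property test).

## Readouts

- phosphorylated fraction: sum of the six GRK-phosphorylated species;
- surface fraction: sum of the six plasma-membrane species;
- internalized fraction: ArrR_gi + R_gi + R_i;
- active fraction: R_s + R\*L_s + w·(R_g\*L_s + R_gs) with w = 0.7 by
  default. The 0.7 weight reflects the reduced coupling of phosphorylated
  receptor; the unweighted reading (w = 1) is available since published
  activity curves do not pin the weight down. Desensitization extent is
  100 − active percent with the naive state at 100 %.

Normalization modes mirror assay conventions: percent of the t = 0 value
(surface receptor), percent of the value at the agonist→antagonist switch
(dephosphorylation), or percent of an external reference maximum
(phosphorylation relative to saturating epinephrine). Initial rates are
least-squares slopes over a 0.5-min window starting 0.05 min after agonist
addition, letting the fast binding step (relaxation time ≈ 1/504 min)
equilibrate first.

## Memory metrics

Per pulse, the desensitization extent is 100 minus the minimum active
percent within that pulse's agonist-on window (the trough of the activity
trace). The memory index is pulse-2 extent minus pulse-1 extent. Two
geometry choices were open and are fixed as follows:

- Inter-pulse decay sweeps use the default 0.5-min pulses with intervals
  spanning 1–120 min.
- The dephosphorylation-fold ablation sweep uses paired 6-s (0.1-min)
  pulses 1 min apart, scaling k2b = k7f = k10f together 2–50-fold.

The raw memory index contains a small phosphorylation-independent floor:
basal internalization (k11b) moves receptor off the surface during the
inter-pulse interval regardless of stimulation history. Where the
phospho-dependent memory itself is at issue, a control train with k2f = 0
(no phosphorylation at all) is subtracted; the residual is the memory
attributable to accumulated surface phosphorylation. Under the sweep
geometry this residual falls to 17 % of baseline at 50-fold accelerated
dephosphorylation while 2–20-fold retain 50–96 % — slow dephosphorylation
is what stores the memory, and only an extreme phosphatase upregulation
erases it.

## Numerics

Rates span 0.004–500/min, so each segment is moderately stiff; segments
are integrated with scipy's LSODA at rtol 1e-10 / atol 1e-12 and sampled
every 0.01 min by default (0.005 min or finer for sub-minute pulses).
Because each segment is linear time-invariant, an independent oracle —
expm(A·t)·y0 with A assembled from a declarative reaction table, distinct
from the hand-written derivative code — provides exact solutions; stepper
and oracle agree to better than 1e-8 per component on randomized rate/state
cases and on all standard protocols. States passed to the right-hand side
are clipped at zero to guard against harmless sub-tolerance undershoot; a
component below −1e-9 aborts the run. Mass conservation holds to ≈1e-14
per step. The model has no randomness anywhere; outputs are deterministic
byte-for-byte for a fixed configuration.

Sensitivity scans vary each of 17 parameters (the 16 non-ligand rate
constants plus the resolved k2f) by folds {1/20, 1/10, 1/5, 1/2, 2, 5, 10,
20}, reporting deviations from the unperturbed simulation at the protocol's
sample times. Deviations are baseline-relative rather than relative to
experimental data points, which carries the same information for testing
directionally.

The acceptance script runs each quantity at the protocol sizes stated in
its docstrings: a 10-cycle 0.5/0.5-min pulse train (the figure-scale
duration of the rapid-stimulation scenario), 15-min sustained protocols,
a 35-min dephosphorylation time course, and a 10-min internalization
window; each completes in well under a second.

## Limitations

The model describes the GRK module only: PKA phosphorylation of the
receptor, adenylyl cyclase, cAMP and PDE dynamics are absent, so behavior
at low agonist concentrations (where PKA dominates) is not captured, and
"activity" maps directly to receptor species rather than to downstream
cyclase output. Spontaneous receptor activation, intermediate
phosphorylation states, explicit arrestin/GRK pools, receptor synthesis
and ligand-independent internalization are likewise out of scope. The
variant comparison and memory analyses are in-silico predictions
conditioned on the default rate constants; they inherit those constants'
experimental uncertainty.
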