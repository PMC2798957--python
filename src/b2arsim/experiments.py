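"""Prebuilt in-silico experiments: standard protocols, model variants,
pulse-train memory analyses, sensitivity scans and partial-agonist panels.

The six model variants toggle where the receptor can be dephosphorylated
(plasma membrane via k2b/k7f, endosome via k10f) and whether phosphorylated
receptor may recycle (k13f), probing which topologies can reproduce measured
dephosphorylation kinetics.

The pulse-train machinery quantifies "cellular memory": because surface
dephosphorylation is slow relative to arrestin cycling, phosphorylated
receptor accumulates across brief agonist pulses, so later pulses
desensitize faster and more deeply even after apparent resensitization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import (
    AGONISTS,
    LIGAND_RATE_NAMES,
    AgonistSpec,
    LigandEnvironment,
    RateSet,
    naive_state,
)
from .readouts import (
    READOUTS,
    active_fraction,
    internalized_fraction,
    phosphorylated_fraction,
)
from .simulator import Protocol, ProtocolSegment, Trajectory, run_protocol

__all__ = [
    "VARIANTS",
    "build_variant",
    "build_standard_protocol",
    "PulseTrainSpec",
    "PulseTrainResult",
    "run_pulse_train",
    "memory_index",
    "interpulse_decay",
    "SCANNABLE_RATES",
    "sensitivity_scan",
    "partial_agonist_panel",
    "DEPHOSPHORYLATION_RATES",
]

#: Rate constants zeroed by each model variant (A is the default topology).
VARIANTS: dict[str, tuple[str, ...]] = {
    "A": (),
    "B": ("k2b", "k7f"),            # no plasma-membrane dephosphorylation
    "C": ("k13f",),                 # no recycling of phosphorylated receptor
    "D": ("k10f",),                 # no endosomal dephosphorylation
    "E": ("k10f", "k13f"),
    "F": ("k2b", "k7f", "k13f"),    # the classical-dogma topology
}

#: The three dephosphorylation rate constants (scaled together in the
#: memory-ablation sweep).
DEPHOSPHORYLATION_RATES = ("k2b", "k7f", "k10f")

#: Parameters included in univariate sensitivity scans: every rate except
#: ligand binding/unbinding, plus the resolved GRK phosphorylation rate k2f.
SCANNABLE_RATES: tuple[str, ...] = ("k2f",) + tuple(
    name for name in RateSet().to_dict() if name not in LIGAND_RATE_NAMES
)

#: Univariate fold changes applied above and below the default rates.
DEFAULT_FOLDS = (1 / 20, 1 / 10, 1 / 5, 1 / 2, 2, 5, 10, 20)


def build_variant(name: str, base: RateSet | None = None) -> RateSet:
    """Return the base rate set with the variant's rates zeroed."""
    if name not in VARIANTS:
        raise ValueError(f"unknown model variant {name!r}; expected one of A-F")
    base = base if base is not None else RateSet()
    zeroed = VARIANTS[name]
    return base.replace(**{k: 0.0 for k in zeroed}) if zeroed else base


def _agonist(agonist: str | AgonistSpec) -> AgonistSpec:
    if isinstance(agonist, AgonistSpec):
        return agonist
    try:
        return AGONISTS[agonist]
    except KeyError:
        raise ValueError(f"unknown agonist {agonist!r}") from None


def _env(agonist, concentration, antagonist=False) -> LigandEnvironment:
    return LigandEnvironment(_agonist(agonist), concentration, antagonist)


def build_standard_protocol(
    experiment: str,
    agonist: str | AgonistSpec = "isoproterenol",
    concentration: float = 1000.0,
    sample_interval: float = 0.01,
    **params,
) -> Protocol:
    """Construct one of the standard stimulation protocols.

    ``phosphorylation``      sustained agonist (default 30 min).
    ``dephosphorylation``    5 min agonist, then antagonist (propranolol
                             block: association rates cut 100,000-fold).
    ``internalization``      sustained agonist (default 20 min).
    ``recycling``            20 min agonist, then plain rapid washout.
    ``desensitization``      sustained agonist (default 15 min).
    ``resensitization``      15 min agonist, then antagonist (metoprolol).
    Durations are configurable via ``treat`` / ``follow`` keyword arguments.
    """
    on = _env(agonist, concentration)
    block = _env(agonist, concentration, antagonist=True)

    if experiment == "phosphorylation":
        segs = [ProtocolSegment(params.get("treat", 30.0), on)]
    elif experiment == "dephosphorylation":
        segs = [
            ProtocolSegment(params.get("treat", 5.0), on),
            ProtocolSegment(params.get("follow", 30.0), block),
        ]
    elif experiment == "internalization":
        segs = [ProtocolSegment(params.get("treat", 20.0), on)]
    elif experiment == "recycling":
        segs = [
            ProtocolSegment(params.get("treat", 20.0), on),
            ProtocolSegment(params.get("follow", 40.0), LigandEnvironment()),
        ]
    elif experiment == "desensitization":
        segs = [ProtocolSegment(params.get("treat", 15.0), on)]
    elif experiment == "resensitization":
        segs = [
            ProtocolSegment(params.get("treat", 15.0), on),
            ProtocolSegment(params.get("follow", 45.0), block),
        ]
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return Protocol(segs, sample_interval=sample_interval)


@dataclass(frozen=True)
class PulseTrainSpec:
    """A periodic agonist pulse train.

    Defaults follow the rapid-stimulation paradigm: 0.5-min pulses of 1 uM
    isoproterenol separated by 0.5-min washouts with instantaneous agonist
    dissociation.  ``washout_mode`` may be "instantaneous" or "plain"
    (dissociation at the ligand off-rate).
    """

    pulse_duration: float = 0.5
    washout_duration: float = 0.5
    n_pulses: int = 3
    agonist: str | AgonistSpec = "isoproterenol"
    concentration: float = 1000.0
    washout_mode: str = "instantaneous"
    sample_interval: float = 0.005

    def __post_init__(self) -> None:
        if self.pulse_duration <= 0 or self.washout_duration <= 0:
            raise ValueError("pulse and washout durations must be > 0")
        if self.n_pulses < 1:
            raise ValueError("need at least one pulse")
        if self.washout_mode not in ("instantaneous", "plain"):
            raise ValueError(f"unknown washout mode {self.washout_mode!r}")

    def to_protocol(self) -> Protocol:
        on = _env(self.agonist, self.concentration)
        entry = (
            "instantaneous_dissociation"
            if self.washout_mode == "instantaneous"
            else "none"
        )
        segs: list[ProtocolSegment] = []
        for _ in range(self.n_pulses):
            segs.append(ProtocolSegment(self.pulse_duration, on))
            segs.append(
                ProtocolSegment(
                    self.washout_duration, LigandEnvironment(), entry_action=entry
                )
            )
        dt = min(self.sample_interval, self.pulse_duration / 10, self.washout_duration / 10)
        return Protocol(segs, sample_interval=dt)


@dataclass
class PulseTrainResult:
    """Per-pulse metrics plus the full trajectory."""

    metrics: pd.DataFrame  # pulse, desensitization_extent, peak_phospho_pct, internalized_end_pct
    trajectory: Trajectory
    spec: PulseTrainSpec


def run_pulse_train(
    spec: PulseTrainSpec,
    rates: RateSet | None = None,
    *,
    rate_scales: Mapping[str, float] | None = None,
) -> PulseTrainResult:
    """Simulate a pulse train from the naive state and score each pulse.

    Desensitization extent per pulse is 100 minus the minimum active-receptor
    percent reached within that pulse's agonist-on window (the trough of the
    activity trace); peak phosphorylated percent and the internalized percent
    at pulse end are reported alongside.
    """
    rates = rates if rates is not None else RateSet()
    traj = run_protocol(
        naive_state(), spec.to_protocol(), rates, rate_scales=rate_scales
    )
    period = spec.pulse_duration + spec.washout_duration
    rows = []
    for p in range(spec.n_pulses):
        t0 = p * period
        win = traj.window(t0, t0 + spec.pulse_duration)
        active_pct = 100.0 * np.asarray(active_fraction(win.states))
        phospho_pct = 100.0 * np.asarray(phosphorylated_fraction(win.states))
        internalized_pct = 100.0 * np.asarray(internalized_fraction(win.states))
        rows.append(
            {
                "pulse": p + 1,
                "desensitization_extent": 100.0 - active_pct.min(),
                "peak_phospho_pct": phospho_pct.max(),
                "internalized_end_pct": internalized_pct[-1],
            }
        )
    return PulseTrainResult(pd.DataFrame(rows), traj, spec)


def memory_index(result: PulseTrainResult) -> float:
    """Desensitization extent of pulse 2 minus pulse 1; positive = memory."""
    m = result.metrics
    if len(m) < 2:
        raise ValueError("memory index requires at least two pulses")
    d = m["desensitization_extent"].to_numpy()
    return float(d[1] - d[0])


def interpulse_decay(
    spec: PulseTrainSpec,
    intervals: Sequence[float],
    rates: RateSet | None = None,
    *,
    rate_scales: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Memory index of a paired-pulse run for each inter-pulse interval.

    Longer intervals allow more surface dephosphorylation between pulses, so
    the memory index decays toward zero.
    """
    import dataclasses as _dc

    rows = []
    for interval in intervals:
        if interval <= 0:
            raise ValueError("inter-pulse intervals must be > 0")
        s = _dc.replace(spec, washout_duration=float(interval), n_pulses=max(spec.n_pulses, 2))
        res = run_pulse_train(s, rates, rate_scales=rate_scales)
        rows.append({"interval_min": float(interval), "memory_index": memory_index(res)})
    return pd.DataFrame(rows)


def sensitivity_scan(
    base: RateSet,
    protocol: Protocol,
    readout: str = "active",
    folds: Iterable[float] = DEFAULT_FOLDS,
    parameters: Sequence[str] | None = None,
    y0: np.ndarray | None = None,
) -> pd.DataFrame:
    """Univariate fold-change scan of the non-ligand rate constants.

    Each parameter is scaled by each fold in turn (ligand binding and
    unbinding rates are never scanned; "k2f" scales the resolved
    phosphorylation rate).  Returns a tidy table of the readout along the
    protocol for the perturbed run, the baseline, and their difference.
    """
    parameters = tuple(parameters) if parameters is not None else SCANNABLE_RATES
    bad = set(parameters) & set(LIGAND_RATE_NAMES)
    if bad:
        raise ValueError(f"ligand rates are excluded from scans: {sorted(bad)}")
    fn = READOUTS[readout]
    y0 = y0 if y0 is not None else naive_state()

    baseline = run_protocol(y0, protocol, base)
    base_vals = np.asarray(fn(baseline.states))

    frames = []
    for param in parameters:
        for fold in folds:
            if fold == 1:
                vals = base_vals
            else:
                traj = run_protocol(y0, protocol, base, rate_scales={param: fold})
                vals = np.asarray(fn(traj.states))
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": param,
                        "fold": float(fold),
                        "time_min": baseline.times,
                        "readout": readout,
                        "value": vals,
                        "baseline": base_vals,
                        "deviation": vals - base_vals,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def partial_agonist_panel(
    agonists: Sequence[str | AgonistSpec] | None = None,
    experiments: Sequence[str] = ("phosphorylation", "internalization", "desensitization"),
    concentration: float = 10_000.0,
    sample_interval: float = 0.05,
    rates: RateSet | None = None,
    use_arrestin_scales: bool = True,
) -> pd.DataFrame:
    """Simulate the standard readouts for a panel of (partial) agonists.

    All ligands are run at a saturating epinephrine-equivalent concentration
    (default 10 uM) with epinephrine's Kd and base phosphorylation rate, so
    coupling efficiency alpha — and, for salmeterol, the altered arrestin
    on/off rates — carries the entire between-agonist difference.  With
    ``use_arrestin_scales=False`` the panel gives the alpha-only prediction.
    """
    if agonists is None:
        agonists = [n for n in AGONISTS if n != "ISO"]
    rates = rates if rates is not None else RateSet()
    reference = AGONISTS["epinephrine"]

    frames = []
    for item in agonists:
        spec = _agonist(item)
        eff = AgonistSpec(
            spec.name,
            Kd=reference.Kd,
            alpha=spec.alpha,
            base_phos_rate=reference.base_phos_rate,
            arrestin_on_scale=spec.arrestin_on_scale if use_arrestin_scales else 1.0,
            arrestin_off_scale=spec.arrestin_off_scale if use_arrestin_scales else 1.0,
        )
        for experiment in experiments:
            protocol = build_standard_protocol(
                experiment, eff, concentration, sample_interval=sample_interval
            )
            traj = run_protocol(naive_state(), protocol, rates)
            readout = {
                "phosphorylation": "phosphorylated",
                "internalization": "internalized",
                "desensitization": "active",
            }.get(experiment, "active")
            vals = np.asarray(READOUTS[readout](traj.states))
            frames.append(
                pd.DataFrame(
                    {
                        "agonist": spec.name,
                        "alpha": spec.alpha,
                        "experiment": experiment,
                        "time_min": traj.times,
                        "readout": readout,
                        "value": vals,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
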