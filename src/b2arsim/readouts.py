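"""Observable quantities derived from simulated trajectories.

Each fraction readout mirrors a biochemical measurement: phosphorylated
fraction the phosphosite-antibody signal, surface fraction a hydrophilic
antagonist binding assay, active fraction the receptor species competent to
stimulate adenylyl cyclase.  GRK-phosphorylated surface receptor is assumed
to retain partial activity (default weight 0.7); arrestin-bound and
internalized receptor are fully uncoupled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    INTERNALIZED_SPECIES,
    PHOSPHORYLATED_SPECIES,
    SURFACE_SPECIES,
    species_index,
)
from .simulator import Trajectory

__all__ = [
    "ReadoutSeries",
    "NormalizationError",
    "phosphorylated_fraction",
    "surface_fraction",
    "active_fraction",
    "internalized_fraction",
    "desensitization_extent",
    "series",
    "normalize",
    "initial_rate",
    "READOUTS",
]

#: Default residual signaling activity of GRK-phosphorylated surface
#: receptor relative to the naive receptor.
PHOSPHO_ACTIVITY = 0.7


class NormalizationError(ValueError):
    """Normalization reference is zero or undefined."""


def _sum_species(states: np.ndarray, names) -> np.ndarray | float:
    states = np.asarray(states, dtype=float)
    idx = [species_index(n) for n in names]
    return states[..., idx].sum(axis=-1)


def phosphorylated_fraction(states: np.ndarray) -> np.ndarray | float:
    """Sum of the six GRK-phosphorylated species, surface or internal."""
    return _sum_species(states, PHOSPHORYLATED_SPECIES)


def surface_fraction(states: np.ndarray) -> np.ndarray | float:
    """Sum of all plasma-membrane receptor species."""
    return _sum_species(states, SURFACE_SPECIES)


def internalized_fraction(states: np.ndarray) -> np.ndarray | float:
    """Sum of endosomal species (degraded receptor excluded)."""
    return _sum_species(states, INTERNALIZED_SPECIES)


def active_fraction(
    states: np.ndarray, phospho_activity: float = PHOSPHO_ACTIVITY
) -> np.ndarray | float:
    """Signaling-competent receptor: Rs + R*Ls + w (Rg*Ls + Rgs).

    Phosphorylated surface receptor contributes with weight ``w``
    (default 0.7); arrestin-bound and internalized species contribute
    nothing.  ``phospho_activity=1.0`` gives the unweighted reading.
    """
    if not 0.0 <= phospho_activity <= 1.0:
        raise ValueError("phospho_activity must be in [0, 1]")
    naive = _sum_species(states, ("Rs", "RstarLs"))
    phospho = _sum_species(states, ("RgstarLs", "Rgs"))
    return naive + phospho_activity * phospho


def desensitization_extent(
    states: np.ndarray, phospho_activity: float = PHOSPHO_ACTIVITY
) -> np.ndarray | float:
    """100 minus active-receptor percent (naive state = 100 %)."""
    return 100.0 * (1.0 - active_fraction(states, phospho_activity))


#: Named readout functions operating on state arrays.
READOUTS = {
    "phosphorylated": phosphorylated_fraction,
    "surface": surface_fraction,
    "internalized": internalized_fraction,
    "active": active_fraction,
}


@dataclass
class ReadoutSeries:
    """A sampled derived observable with its normalization convention."""

    times: np.ndarray
    values: np.ndarray
    name: str
    normalization: str = "fraction"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "value": self.values,
                "readout": self.name,
                "normalization": self.normalization,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def series(trajectory: Trajectory, readout: str, **kwargs) -> ReadoutSeries:
    """Evaluate a named readout along a trajectory (as fractions)."""
    fn = READOUTS[readout]
    return ReadoutSeries(trajectory.times, fn(trajectory.states, **kwargs), readout)


def normalize(
    s: ReadoutSeries,
    mode: str,
    *,
    switch_time: float | None = None,
    reference_max: float | None = None,
) -> ReadoutSeries:
    """Rescale a series to percent of a designated reference value.

    ``percent_of_t0`` uses the first sample (e.g. surface receptor at time
    zero = 100 %); ``percent_of_switch`` the value at ``switch_time`` (e.g.
    phosphorylation at the agonist-to-antagonist switch); and
    ``percent_of_reference_max`` an externally supplied maximum such as the
    peak 10 uM epinephrine phosphorylation.
    """
    if mode == "percent_of_t0":
        ref = float(s.values[0])
    elif mode == "percent_of_switch":
        if switch_time is None:
            raise NormalizationError("percent_of_switch requires switch_time")
        i = int(np.argmin(np.abs(s.times - switch_time)))
        ref = float(s.values[i])
    elif mode == "percent_of_reference_max":
        if reference_max is None:
            raise NormalizationError("percent_of_reference_max requires reference_max")
        ref = float(reference_max)
    else:
        raise NormalizationError(f"unknown normalization mode {mode!r}")
    if ref == 0:
        raise NormalizationError("normalization reference is zero")
    return ReadoutSeries(s.times, 100.0 * s.values / ref, s.name, mode)


def initial_rate(
    s: ReadoutSeries, window: float = 0.5, offset: float = 0.05
) -> float:
    """Least-squares initial slope of a fraction readout, /min.

    Fit over ``[offset, offset + window]``; the default 0.05-min offset lets
    fast ligand binding (relaxation time about 1/504 min) equilibrate before
    the slope of the slower downstream readout is measured.
    """
    t0, t1 = offset, offset + window
    if t1 > s.times[-1] + 1e-9:
        raise ValueError("fit window exceeds the series span")
    mask = (s.times >= t0 - 1e-9) & (s.times <= t1 + 1e-9)
    t, v = s.times[mask], s.values[mask]
    slope = np.polyfit(t, v, 1)[0]
    return float(slope)
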