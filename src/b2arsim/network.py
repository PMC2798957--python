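"""Species, reactions, rate constants and the mass-action right-hand side.

The model tracks a single pool of beta-2 adrenergic receptor (β2AR)
distributed over ten molecular species: naive surface receptor, the
agonist-activated complex, GRK-phosphorylated forms with and without bound
agonist and/or arrestin, internalized forms, and a degraded sink.  All
reactions are (pseudo-)first order — GRK and arrestin are assumed to be in
large excess and enter only through rate constants — so within any constant
ligand environment the system is linear and closed: receptor mass is
conserved exactly.

Amounts are dimensionless fractions of total receptor (R_total = 1), time is
in minutes, ligand concentrations in nM.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "SPECIES",
    "SURFACE_SPECIES",
    "PHOSPHORYLATED_SPECIES",
    "INTERNALIZED_SPECIES",
    "REACTIONS",
    "LIGAND_RATE_NAMES",
    "ANTAGONIST_ATTENUATION",
    "RateSet",
    "AgonistSpec",
    "LigandEnvironment",
    "AGONISTS",
    "WASHOUT",
    "naive_state",
    "state",
    "occupancy",
    "phosphorylation_rate",
    "effective_rates",
    "derivatives",
]

#: Canonical species order.  Subscript ``s`` = plasma membrane (surface),
#: ``i`` = internalized; ``g`` = GRK-phosphorylated; ``L`` = agonist bound;
#: ``Arr`` = arrestin bound; ``star`` marks the active receptor conformation.
SPECIES = (
    "Rs",
    "RstarLs",
    "RgstarLs",
    "ArrRgstarLs",
    "ArrRgs",
    "Rgs",
    "ArrRgi",
    "Rgi",
    "Ri",
    "Rdegraded",
)

_IDX = {name: i for i, name in enumerate(SPECIES)}

#: Plasma-membrane species (surface receptor readout).
SURFACE_SPECIES = ("Rs", "RstarLs", "RgstarLs", "ArrRgstarLs", "ArrRgs", "Rgs")

#: The six GRK-phosphorylated species (phospho-antibody readout).
PHOSPHORYLATED_SPECIES = ("RgstarLs", "ArrRgstarLs", "ArrRgs", "Rgs", "ArrRgi", "Rgi")

#: Endosomal species; the degraded sink is tracked separately.
INTERNALIZED_SPECIES = ("ArrRgi", "Rgi", "Ri")

#: Unidirectional first-order edges as (substrate, product, rate-constant key).
#: This declarative table drives the linear-algebra oracle and the SBML
#: export; :func:`derivatives` is written out by hand, independently.
REACTIONS = (
    ("Rs", "RstarLs", "k1f"),          # agonist binding
    ("RstarLs", "Rs", "k1b"),          # agonist dissociation
    ("RstarLs", "RgstarLs", "k2f"),    # GRK phosphorylation
    ("RgstarLs", "RstarLs", "k2b"),    # surface dephosphorylation
    ("RgstarLs", "ArrRgstarLs", "k3f"),  # arrestin binding
    ("ArrRgstarLs", "RgstarLs", "k3b"),  # arrestin off (agonist-bound)
    ("ArrRgstarLs", "ArrRgs", "k4f"),  # agonist off the arrestin complex
    ("ArrRgs", "ArrRgstarLs", "k4b"),  # agonist re-binding
    ("RgstarLs", "Rgs", "k5f"),        # agonist off the phospho-receptor
    ("Rgs", "RgstarLs", "k5b"),        # agonist re-binding
    ("ArrRgs", "Rgs", "k6f"),          # arrestin off (ligand-free, surface)
    ("Rgs", "Rs", "k7f"),              # surface dephosphorylation
    ("ArrRgstarLs", "ArrRgi", "k8f"),  # internalization (ligand released)
    ("ArrRgi", "Rgi", "k9f"),          # arrestin off (internalized)
    ("Rgi", "Ri", "k10f"),             # internal dephosphorylation
    ("Ri", "Rs", "k11f"),              # recycling
    ("Rs", "Ri", "k11b"),              # basal internalization of Rs
    ("ArrRgs", "ArrRgi", "k12f"),      # basal internalization of ArrRgs
    ("Rgi", "Rgs", "k13f"),            # recycling of phospho-receptor
    ("Rgs", "Rgi", "k13b"),            # basal internalization of Rgs
    ("ArrRgi", "Rdegraded", "k14f"),   # degradation
    ("Rgi", "Rdegraded", "k15f"),      # degradation
    ("Ri", "Rdegraded", "k16f"),       # degradation
)

#: Ligand association rate constants, attenuated together by a competitive
#: antagonist and zeroed on washout.
LIGAND_ASSOCIATION = ("k1f", "k4b", "k5b")

#: All ligand binding/unbinding rates (excluded from sensitivity scans).
LIGAND_RATE_NAMES = ("k1f", "k1b", "k4f", "k4b", "k5f", "k5b")

#: Competitive antagonist reduces agonist association this many fold.
ANTAGONIST_ATTENUATION = 1e5


class InvalidParameterError(ValueError):
    """A kinetic parameter or ligand argument is out of its valid domain."""


class InvalidStateError(ValueError):
    """A state vector violates non-negativity or shape requirements."""


@dataclass(frozen=True)
class RateSet:
    """The 22 fixed rate constants of the trafficking network, in /min.

    The GRK phosphorylation rate ``k2f`` is not stored here: it depends on
    the agonist and its concentration and is resolved per ligand environment
    by :func:`effective_rates`.
    """

    k1f: float = 500.0
    k1b: float = 4.0
    k2b: float = 0.036
    k3f: float = 27.0
    k3b: float = 4.0
    k4f: float = 4.0
    k4b: float = 500.0
    k5f: float = 4.0
    k5b: float = 500.0
    k6f: float = 11.0
    k7f: float = 0.036
    k8f: float = 0.22
    k9f: float = 11.0
    k10f: float = 0.036
    k11f: float = 0.09
    k11b: float = 0.0085
    k12f: float = 0.0085
    k13f: float = 0.09
    k13b: float = 0.0085
    k14f: float = 0.004
    k15f: float = 0.004
    k16f: float = 0.004

    def __post_init__(self) -> None:
        for name, value in self.to_dict().items():
            if value < 0:
                raise InvalidParameterError(f"rate {name} must be >= 0, got {value}")

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def replace(self, **overrides: float) -> "RateSet":
        """Return a copy with the named rate constants replaced."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise InvalidParameterError(
                f"unknown rate constant(s): {', '.join(sorted(unknown))}"
            )
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "RateSet":
        return cls().replace(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class AgonistSpec:
    """A ligand acting on the receptor.

    Parameters
    ----------
    Kd
        Equilibrium dissociation constant, nM.
    alpha
        Coupling efficiency relative to epinephrine (1 for full agonists).
    base_phos_rate
        GRK phosphorylation rate at full occupancy for a full agonist, /min.
    arrestin_on_scale, arrestin_off_scale
        Multipliers of the arrestin binding (k3f) and dissociation (k3b)
        rates from the agonist-bound complex; used for ligands such as
        salmeterol that stabilize a receptor state with reduced arrestin
        affinity.
    """

    name: str
    Kd: float
    alpha: float
    base_phos_rate: float = 1.4
    arrestin_on_scale: float = 1.0
    arrestin_off_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise InvalidParameterError(f"Kd must be > 0, got {self.Kd}")
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.base_phos_rate < 0:
            raise InvalidParameterError("base_phos_rate must be >= 0")
        if self.arrestin_on_scale <= 0 or self.arrestin_off_scale <= 0:
            raise InvalidParameterError("arrestin affinity scales must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Shipped agonist library.  Coupling efficiencies are relative to
#: epinephrine; partial agonists inherit epinephrine's Kd and base
#: phosphorylation rate, with concentration fixed at saturation in the
#: partial-agonism panel, so only alpha (and arrestin scales) distinguish
#: them.  Salmeterol carries a ten-fold slower arrestin on-rate and ten-fold
#: faster off-rate, reflecting its reduced-arrestin-affinity receptor state.
AGONISTS: dict[str, AgonistSpec] = {
    a.name: a
    for a in (
        AgonistSpec("epinephrine", Kd=450.0, alpha=1.0, base_phos_rate=1.4),
        AgonistSpec("isoproterenol", Kd=283.0, alpha=1.0, base_phos_rate=0.7),
        AgonistSpec("fenoterol", Kd=450.0, alpha=0.66),
        AgonistSpec("formoterol", Kd=450.0, alpha=0.63),
        AgonistSpec("terbutaline", Kd=450.0, alpha=0.33),
        AgonistSpec("zinterol", Kd=450.0, alpha=0.33),
        AgonistSpec("albuterol", Kd=450.0, alpha=0.25),
        AgonistSpec(
            "salmeterol",
            Kd=450.0,
            alpha=0.13,
            arrestin_on_scale=0.1,
            arrestin_off_scale=10.0,
        ),
        AgonistSpec("dobutamine", Kd=450.0, alpha=0.04),
        AgonistSpec("ephedrine", Kd=450.0, alpha=0.03),
    )
}
AGONISTS["ISO"] = AGONISTS["isoproterenol"]


@dataclass(frozen=True)
class LigandEnvironment:
    """Extracellular ligand condition during one protocol segment."""

    agonist: AgonistSpec | None = None
    concentration: float = 0.0
    antagonist_present: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InvalidParameterError("concentration must be >= 0")
        if self.concentration > 0 and self.agonist is None:
            raise InvalidParameterError("nonzero concentration requires an agonist")


#: Plain washout: no ligand; bound agonist dissociates at its off-rate.
WASHOUT = LigandEnvironment()


def naive_state(total: float = 1.0) -> np.ndarray:
    """All receptor naive on the plasma membrane (Rs = total)."""
    y = np.zeros(len(SPECIES))
    y[_IDX["Rs"]] = total
    return y


def state(**fractions: float) -> np.ndarray:
    """Build a state vector from named species fractions (others zero)."""
    y = np.zeros(len(SPECIES))
    for name, value in fractions.items():
        if name not in _IDX:
            raise InvalidStateError(f"unknown species {name!r}")
        y[_IDX[name]] = value
    return y


def species_index(name: str) -> int:
    return _IDX[name]


def occupancy(L: float, Kd: float) -> float:
    """Equilibrium fractional receptor occupancy L/(L + Kd).

    Monotone nondecreasing in ``L``; 0 at no ligand, 0.5 at L = Kd.
    """
    if Kd <= 0:
        raise InvalidParameterError(f"Kd must be > 0, got {Kd}")
    if L < 0:
        raise InvalidParameterError(f"concentration must be >= 0, got {L}")
    return L / (L + Kd)


def phosphorylation_rate(agonist: AgonistSpec, L: float) -> float:
    """Pseudo-first-order GRK phosphorylation rate, /min.

    alpha * occupancy(L, Kd) * base rate: occupancy makes the rate agonist-
    concentration dependent (occupancy is rate-determining for strong
    agonists) and alpha scales partial agonists relative to epinephrine.
    """
    return agonist.alpha * occupancy(L, agonist.Kd) * agonist.base_phos_rate


def effective_rates(
    rates: RateSet,
    env: LigandEnvironment,
    rate_scales: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Resolve the 23 pseudo-first-order rate constants for an environment.

    Ligand association rates (k1f, k4b, k5b) are zero on washout, their
    stored values when agonist is present, and attenuated 100,000-fold by a
    competitive antagonist.  k2f is the occupancy- and efficacy-scaled GRK
    phosphorylation rate; k3f/k3b carry the agonist's arrestin-affinity
    scales.  ``rate_scales`` applies final multiplicative perturbations (for
    sensitivity analysis; a scale on "k2f" perturbs the resolved value).
    """
    r = rates.to_dict()
    if env.concentration > 0:
        assert env.agonist is not None
        r["k2f"] = phosphorylation_rate(env.agonist, env.concentration)
    else:
        for name in LIGAND_ASSOCIATION:
            r[name] = 0.0
        r["k2f"] = 0.0
    if env.antagonist_present:
        for name in LIGAND_ASSOCIATION:
            r[name] = r[name] / ANTAGONIST_ATTENUATION
    if env.agonist is not None:
        r["k3f"] *= env.agonist.arrestin_on_scale
        r["k3b"] *= env.agonist.arrestin_off_scale
    if rate_scales:
        for name, scale in rate_scales.items():
            if name not in r:
                raise InvalidParameterError(f"unknown rate constant {name!r}")
            r[name] *= scale
    return r


def derivatives(y: np.ndarray, r: Mapping[str, float]) -> np.ndarray:
    """Mass-action time derivative of the state vector, /min.

    Written out reaction by reaction; the component sum is identically zero
    (closed system).  ``r`` is a resolved rate table from
    :func:`effective_rates`.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (len(SPECIES),):
        raise InvalidStateError(f"state must have shape ({len(SPECIES)},)")
    if np.any(y < 0):
        raise InvalidStateError("state components must be >= 0")

    Rs, RstarLs, RgstarLs, ArrRgstarLs, ArrRgs, Rgs, ArrRgi, Rgi, Ri, _ = y

    dRs = (
        -r["k1f"] * Rs
        + r["k1b"] * RstarLs
        + r["k7f"] * Rgs
        + r["k11f"] * Ri
        - r["k11b"] * Rs
    )
    dRstarLs = (
        r["k1f"] * Rs
        - r["k1b"] * RstarLs
        - r["k2f"] * RstarLs
        + r["k2b"] * RgstarLs
    )
    dRgstarLs = (
        r["k2f"] * RstarLs
        - r["k2b"] * RgstarLs
        - r["k3f"] * RgstarLs
        + r["k3b"] * ArrRgstarLs
        - r["k5f"] * RgstarLs
        + r["k5b"] * Rgs
    )
    dArrRgstarLs = (
        r["k3f"] * RgstarLs
        - r["k3b"] * ArrRgstarLs
        - r["k4f"] * ArrRgstarLs
        + r["k4b"] * ArrRgs
        - r["k8f"] * ArrRgstarLs
    )
    dArrRgs = (
        r["k4f"] * ArrRgstarLs
        - r["k4b"] * ArrRgs
        - r["k6f"] * ArrRgs
        - r["k12f"] * ArrRgs
    )
    dRgs = (
        r["k5f"] * RgstarLs
        - r["k5b"] * Rgs
        + r["k6f"] * ArrRgs
        - r["k7f"] * Rgs
        + r["k13f"] * Rgi
        - r["k13b"] * Rgs
    )
    dArrRgi = (
        r["k8f"] * ArrRgstarLs
        + r["k12f"] * ArrRgs
        - r["k9f"] * ArrRgi
        - r["k14f"] * ArrRgi
    )
    dRgi = (
        r["k9f"] * ArrRgi
        - r["k10f"] * Rgi
        - r["k13f"] * Rgi
        + r["k13b"] * Rgs
        - r["k15f"] * Rgi
    )
    dRi = (
        r["k10f"] * Rgi
        - r["k11f"] * Ri
        + r["k11b"] * Rs
        - r["k16f"] * Ri
    )
    dRdeg = r["k14f"] * ArrRgi + r["k15f"] * Rgi + r["k16f"] * Ri

    return np.array(
        [dRs, dRstarLs, dRgstarLs, dArrRgstarLs, dArrRgs, dRgs, dArrRgi, dRgi, dRi, dRdeg]
    )
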