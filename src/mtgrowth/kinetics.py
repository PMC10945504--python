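"""Event-rate laws: lattice context + mechanism mode + parameters -> rates.

Two competing mechanisms of nucleotide action are implemented.  Under the
self-acting (cis) mechanism a tubulin's own bound nucleotide sets how tightly
that tubulin holds onto the lattice; under the interface-acting (trans)
mechanism the nucleotide buried at the dimer:dimer interface sets it.  At the
minus-end the two coincide, because the terminal subunit's nucleotide *is*
the interfacial nucleotide.

Rates follow the standard biochemical conventions for this model family:

* association is first-order in free tubulin, ``on_rate = k_on * [tubulin]``,
  identical for GDP- and GMPCPP-tubulin (no inherent on-rate difference);
* dissociation is ``k_off = k_on * K_D`` with the site affinity K_D set by
  the contact class (longitudinal-only, corner, bucket) and the governing
  nucleotide (strong GTP/GMPCPP vs weak GDP);
* nucleotide exchange at exposed plus-end terminal subunits is rate-limited
  by dissociation of the currently bound nucleotide: GDP leaves at
  ``k_exchange_gdp`` and GMPCPP/GTP leaves ``exchange_ratio``-fold faster
  (12.5-fold, mirroring tubulin's weaker affinity for GMPCPP); the
  replacement is drawn from the free-nucleotide mole fractions.

Lateral bonds are nucleotide-insensitive; only the longitudinal/interfacial
nucleotide modulates affinity.  Bucket sites (two lateral contacts) get their
affinity by free-energy additivity: one lateral bond contributes
ln(K_D_corner / K_D_long), so K_D_bucket = K_D_corner^2 / K_D_long.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .lattice import (
    GDP,
    GMPCPP,
    GTP,
    ContactClass,
    LatticeState,
    Subunit,
    interfacial_nucleotide,
    is_weak,
)

__all__ = [
    "SELF_ACTING",
    "INTERFACE_ACTING",
    "KineticParams",
    "SolutionState",
    "ILLUSTRATIVE_PARAMS",
    "CALIBRATED_PARAMS",
    "governing_nucleotide",
    "site_KD",
    "association_rate",
    "dissociation_rate",
    "sample_incoming_nucleotide",
    "exchange_event_rate",
    "sample_replacement_nucleotide",
]

SELF_ACTING = "self_acting"
INTERFACE_ACTING = "interface_acting"


@dataclass(frozen=True)
class KineticParams:
    """Rate and affinity parameters of the elongation model.

    Units: on-rate constants in uM^-1 s^-1, dissociation constants in uM,
    exchange rate in s^-1.  ``kd_long_gdp / kd_long`` and
    ``kd_corner_gdp / kd_corner`` encode a single GDP weakening factor; a
    warning is raised if the two implied factors differ by more than 10%.
    """

    kon_plus: float = 0.74
    kon_minus: float = 0.31
    kd_long: float = 86.0
    kd_corner: float = 0.025
    kd_long_gdp: float = 3.0e5
    kd_corner_gdp: float = 87.0
    k_exchange_gdp: float = 0.0
    exchange_ratio: float = 12.5
    mechanism: str = INTERFACE_ACTING

    def __post_init__(self) -> None:
        for name in (
            "kon_plus",
            "kon_minus",
            "kd_long",
            "kd_corner",
            "kd_long_gdp",
            "kd_corner_gdp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_exchange_gdp < 0:
            raise ValueError("k_exchange_gdp must be >= 0")
        if self.exchange_ratio <= 0:
            raise ValueError("exchange_ratio must be > 0")
        if self.mechanism not in (SELF_ACTING, INTERFACE_ACTING):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        f_long = self.kd_long_gdp / self.kd_long
        f_corner = self.kd_corner_gdp / self.kd_corner
        if abs(f_long - f_corner) > 0.10 * f_long:
            warnings.warn(
                "GDP weakening factors differ by >10% between longitudinal "
                f"({f_long:.3g}) and corner ({f_corner:.3g}) interfaces",
                stacklevel=2,
            )

    def kon_end(self, polarity: str) -> float:
        return self.kon_plus if polarity == "plus" else self.kon_minus

    # -- parameter-file round-trip ------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "KineticParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: arbitrary affinities chosen only to support elongation at ~1 uM tubulin,
#: used for the mechanism-contrast predictions (GDP 3000-fold weakening)
ILLUSTRATIVE_PARAMS = KineticParams(
    kon_plus=1.0,
    kon_minus=1.0,
    kd_long=100.0,
    kd_corner=0.1,
    kd_long_gdp=3.0e5,
    kd_corner_gdp=300.0,
)

#: parameters calibrated against GMPCPP growth-rate measurements
#: (plus-end constants from the prior-study fit, minus-end on-rate refit;
#: GDP 3500-fold weakening)
CALIBRATED_PARAMS = KineticParams(
    kon_plus=0.74,
    kon_minus=0.31,
    kd_long=86.0,
    kd_corner=0.025,
    kd_long_gdp=3.0e5,
    kd_corner_gdp=87.0,
)


@dataclass(frozen=True)
class SolutionState:
    """Composition of the (inexhaustible) free tubulin/nucleotide reservoir.

    ``frac_gdp_tubulin`` is the fraction of unpolymerized tubulin carrying
    GDP; ``free_frac_gdp`` is the mole fraction of *free nucleotide* that is
    GDP, used when an exchange event picks the replacement nucleotide.
    """

    tubulin_total: float = 1.0
    frac_gdp_tubulin: float = 0.0
    free_frac_gdp: float = 0.0
    strong_species: str = GMPCPP

    def __post_init__(self) -> None:
        if self.tubulin_total < 0:
            raise ValueError("tubulin_total must be >= 0")
        for name in ("frac_gdp_tubulin", "free_frac_gdp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.strong_species not in (GTP, GMPCPP):
            raise ValueError("strong_species must be GTP or GMPCPP")


def governing_nucleotide(state: LatticeState, pf: int, mode: str) -> str:
    """Nucleotide that governs the terminal subunit's lattice affinity.

    Plus-end, interface-acting: the buried interfacial nucleotide.
    Plus-end, self-acting: the terminal subunit's own nucleotide.
    Minus-end: the terminal subunit's own nucleotide under either mode
    (the two mechanisms are equivalent there).
    """
    if state.polarity == "plus" and mode == INTERFACE_ACTING:
        return interfacial_nucleotide(state, pf)
    return state.columns[pf][-1].nucleotide


def site_KD(cls: ContactClass, governing: str, p: KineticParams) -> float:
    """Site affinity (uM) for a contact class under a governing nucleotide.

    One lateral bond is worth the free energy ln(K_D_long / K_D_corner), so
    a site with ``b`` lateral bonds has K_D = K_D_long (K_D_corner/K_D_long)^b:
    longitudinal-only (b=0) -> K_D_long, corner (b=1) -> K_D_corner, bucket
    (b=2) -> K_D_corner^2 / K_D_long, with half-integer b (half-overlapped
    seam partners) interpolating on the free-energy scale.
    """
    if is_weak(governing):
        kd_long, kd_corner = p.kd_long_gdp, p.kd_corner_gdp
    else:
        kd_long, kd_corner = p.kd_long, p.kd_corner
    b = cls.n_lateral
    if b == 0:
        return kd_long
    if b == 1:
        return kd_corner
    if b == 2:
        return kd_corner * kd_corner / kd_long
    return kd_long * (kd_corner / kd_long) ** b


def association_rate(p: KineticParams, sol: SolutionState, polarity: str) -> float:
    """Per-candidate-site association rate, s^-1 (same for either nucleotide)."""
    return p.kon_end(polarity) * sol.tubulin_total


def dissociation_rate(p: KineticParams, polarity: str, kd: float) -> float:
    """Dissociation rate k_off = k_on * K_D with the end-specific k_on."""
    return p.kon_end(polarity) * kd


def sample_incoming_nucleotide(sol: SolutionState, rng: np.random.Generator) -> str:
    """Nucleotide carried by an arriving tubulin."""
    if rng.random() < sol.frac_gdp_tubulin:
        return GDP
    return sol.strong_species


def exchange_event_rate(sub: Subunit, p: KineticParams) -> float:
    """Rate at which the bound nucleotide of an exposed terminal leaves.

    Dissociation of the previously bound nucleotide is rate-limiting, so the
    event rate depends only on what is currently bound: GDP leaves at
    ``k_exchange_gdp``, GMPCPP/GTP ``exchange_ratio``-fold faster.
    """
    if is_weak(sub.nucleotide):
        return p.k_exchange_gdp
    return p.exchange_ratio * p.k_exchange_gdp


def sample_replacement_nucleotide(sol: SolutionState, rng: np.random.Generator) -> str:
    """Replacement drawn from free-nucleotide mole fractions on exchange."""
    if rng.random() < sol.free_frac_gdp:
        return GDP
    return sol.strong_species
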