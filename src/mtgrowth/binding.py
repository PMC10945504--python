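"""Fluorescence-quenching nucleotide affinity assays.

6-thio-GTP quenches tubulin tryptophan fluorescence on binding, so a
titration reports occupancy of the exchangeable site.  Because the analog
also absorbs at the tryptophan emission peak, the raw signal is corrected
for the inner-filter effect against a BSA channel matched for tryptophan
fluorescence, after blank subtraction:

    y = (F_tub - F_blank) / (F_bsa - F_blank)

The quench isotherm is  y = B - A c / (c + K_D^6T)  with amplitude A and
zero-titrant baseline B.  Adding an unlabelled competitor (GMPCPP or GDP)
at fixed 6-thio-GTP unquenches the signal following the competitive model

    y = C + A c_nuc / (c_nuc + K_D^nuc (1 + c_6T / K_D^6T)),

with A constrained to the measured quench amplitude at the fixed 6-thio-GTP
concentration.  All fits are least squares weighted by 1/SEM; SEMs of the
corrected signal come from relative-error propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datasets import FluorescenceDataset

__all__ = [
    "IsothermFit",
    "CompetitionFit",
    "correct_inner_filter",
    "propagate_sem",
    "corrected_signal",
    "fit_isotherm",
    "fit_competition",
]


@dataclass(frozen=True)
class IsothermFit:
    """Quench isotherm parameters: baseline B, amplitude A, K_D of 6-thio-GTP."""

    A: float
    B: float
    KD_6T: float
    stderr_KD: float = float("nan")

    def __post_init__(self) -> None:
        if self.KD_6T <= 0:
            raise ValueError("KD_6T must be > 0")
        if self.A > self.B:
            raise ValueError("amplitude A cannot exceed baseline B")

    def predict(self, conc):
        c = np.asarray(conc, dtype=float)
        return self.B - self.A * c / (c + self.KD_6T)

    def amplitude_at(self, fixed_6T: float) -> float:
        """Realized quench amplitude at a fixed 6-thio-GTP concentration."""
        return self.A * fixed_6T / (fixed_6T + self.KD_6T)


@dataclass(frozen=True)
class CompetitionFit:
    """Competition parameters: quenched baseline C and competitor K_D (uM)."""

    C: float
    KD_nuc: float
    A: float  # constrained amplitude, from the isotherm at the fixed 6T conc
    stderr_KD: float = float("nan")

    def __post_init__(self) -> None:
        if self.KD_nuc <= 0:
            raise ValueError("KD_nuc must be > 0")


def correct_inner_filter(F_tub, F_bsa, F_blank):
    """Inner-filter-corrected signal (blank-subtracted tubulin over BSA)."""
    F_tub = np.asarray(F_tub, dtype=float)
    F_bsa = np.asarray(F_bsa, dtype=float)
    F_blank = np.asarray(F_blank, dtype=float)
    if np.any(F_bsa - F_blank <= 0):
        raise ValueError("F_bsa must exceed F_blank at every point")
    return (F_tub - F_blank) / (F_bsa - F_blank)


def propagate_sem(means, sems, scale: float | np.ndarray = 1.0):
    """SEM of the corrected signal from the channels' relative SEMs.

    sqrt(sum_i (SEM_i / mean_i)^2) * scale, with scale the tubulin/BSA mean
    ratio.  Means must be nonzero.
    """
    means = np.asarray(means, dtype=float)
    sems = np.asarray(sems, dtype=float)
    if np.any(means == 0):
        raise ValueError("zero mean: relative SEM undefined")
    rel2 = (sems / means) ** 2
    return np.sqrt(rel2.sum(axis=0)) * scale


def corrected_signal(ds: FluorescenceDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(conc, y, sem_y) for a titration table, corrected and propagated."""
    t = ds.table
    y = correct_inner_filter(t["F_tub"], t["F_bsa"], t["F_blank"])
    scale = t["F_tub"].to_numpy() / t["F_bsa"].to_numpy()
    sem_y = propagate_sem(
        np.vstack([t["F_bsa"], t["F_tub"], np.where(t["F_blank"] == 0, 1.0, t["F_blank"])]),
        np.vstack([t["sem_bsa"], t["sem_tub"], np.where(t["F_blank"] == 0, 0.0, t["sem_blank"])]),
        scale=np.abs(scale),
    )
    return t["conc_uM"].to_numpy(dtype=float), np.asarray(y), np.asarray(sem_y)


def _weights(sem_y: np.ndarray) -> np.ndarray:
    # 1/SEM weighting; all-zero SEMs (noise-free synthetic data) fall back to OLS
    if np.all(sem_y <= 0):
        return np.ones_like(sem_y)
    floor = sem_y[sem_y > 0].min()
    return np.maximum(sem_y, floor)


def fit_isotherm(ds: FluorescenceDataset) -> IsothermFit:
    """Weighted fit of the quench isotherm; returns (A, B, K_D^6T).

    Warns when the titration does not span the fitted K_D (the estimate is
    then poorly conditioned).
    """
    conc, y, sem_y = corrected_signal(ds)
    if len(conc) < 3:
        raise ValueError("need >= 3 concentrations to fit the isotherm")

    def model(c, A, B, kd):
        return B - A * c / (c + kd)

    # coarse K_D grid for the starting point; A, B from the signal range
    span = y.max() - y.min()
    best = min(
        (np.geomspace(max(conc[conc > 0].min(), 1e-3), conc.max() * 10, 25)),
        key=lambda kd: np.sum((model(conc, span, y.max(), kd) - y) ** 2),
    )
    popt, pcov = curve_fit(
        model,
        conc,
        y,
        p0=[span, y.max(), best],
        sigma=_weights(sem_y),
        bounds=([0, 0, 1e-9], [np.inf, np.inf, np.inf]),
        maxfev=10000,
    )
    A, B, kd = (float(v) for v in popt)
    if not (conc[conc > 0].min() <= kd <= conc.max()):
        warnings.warn(
            f"fitted KD_6T={kd:.3g} uM lies outside the titrated range; "
            "estimate is ill-conditioned",
            stacklevel=2,
        )
    return IsothermFit(A=A, B=B, KD_6T=kd, stderr_KD=float(np.sqrt(pcov[2, 2])))


def fit_competition(ds: FluorescenceDataset, isotherm: IsothermFit) -> CompetitionFit:
    """Weighted competition fit with the amplitude constrained by the isotherm.

    The free parameters are the quenched baseline C and the competitor's
    K_D; A is fixed to the isotherm's quench amplitude at the run's fixed
    6-thio-GTP concentration.
    """
    if not np.isfinite(ds.fixed_6T):
        raise ValueError("competition dataset must set fixed_6T")
    conc, y, sem_y = corrected_signal(ds)
    if np.all(conc == 0):
        raise ValueError("competitor-free data only: KD_nuc unidentifiable")
    A = isotherm.amplitude_at(ds.fixed_6T)
    alpha = 1.0 + ds.fixed_6T / isotherm.KD_6T

    def model(c, C, kd):
        return C + A * c / (c + kd * alpha)

    best = min(
        np.geomspace(1e-3, max(conc.max(), 1.0) * 10, 25),
        key=lambda kd: np.sum((model(conc, y.min(), kd) - y) ** 2),
    )
    popt, pcov = curve_fit(
        model,
        conc,
        y,
        p0=[y.min(), best],
        sigma=_weights(sem_y),
        bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
        maxfev=10000,
    )
    C, kd = float(popt[0]), float(popt[1])
    return CompetitionFit(C=C, KD_nuc=kd, A=A, stderr_KD=float(np.sqrt(pcov[1, 1])))
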