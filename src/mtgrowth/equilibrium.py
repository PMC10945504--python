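"""Competitive nucleotide binding and the minus-end calibration line.

In mixed-nucleotide assays GDP and GMPCPP compete for tubulin's exchangeable
site, so the nucleotide ratio in solution does not directly give the
GDP-/GMPCPP-tubulin fractions.  With both nucleotides far above their
dissociation constants, the GMPCPP-tubulin fraction reduces to

    f_CPP = [GMPCPP] / ([GMPCPP] + [GDP] * r),      r = K_D^GMPCPP / K_D^GDP,

the high-concentration limit of the full competitive-inhibition expression
f_CPP = [CPP] / ([CPP] + K_D^CPP (1 + [GDP]/K_D^GDP)).  Tubulin binds GDP
more tightly than GMPCPP, so r > 1 and small amounts of GDP displace a
disproportionate amount of GMPCPP.

Minus-end growth depends only on the GMPCPP-tubulin concentration (GDP-
tubulin neither adds nor poisons there), which a linear calibration maps to
a growth rate:

    GR_minus = slope * [tubulin_CPP] + intercept        (nm/s)

Fitting measured minus-end rates across GDP titrations to this composite
model, with r the single free parameter, estimates the relative affinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datasets import GrowthRateDataset

__all__ = [
    "NucleotideMix",
    "AffinityRatio",
    "MinusCalibration",
    "fraction_strong_tubulin",
    "fraction_strong_full",
    "free_gdp_fraction",
    "predict_minus_rate",
    "fit_affinity_ratio",
]


@dataclass(frozen=True)
class NucleotideMix:
    """Solution nucleotide composition (uM); gmpcpp + gdp = total."""

    gmpcpp: float
    gdp: float

    def __post_init__(self) -> None:
        if self.gmpcpp < 0 or self.gdp < 0:
            raise ValueError("nucleotide concentrations must be >= 0")

    @property
    def total(self) -> float:
        return self.gmpcpp + self.gdp

    @classmethod
    def from_gdp(cls, gdp: float, total: float = 1000.0) -> "NucleotideMix":
        if not 0 <= gdp <= total:
            raise ValueError(f"gdp must be in [0, {total}] uM")
        return cls(gmpcpp=total - gdp, gdp=gdp)


@dataclass(frozen=True)
class AffinityRatio:
    """r = K_D^GMPCPP / K_D^GDP (dimensionless, > 0; >1 means GDP binds tighter)."""

    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("affinity ratio must be > 0")


@dataclass(frozen=True)
class MinusCalibration:
    """Linear map from GMPCPP-tubulin (uM) to minus-end growth rate (nm/s)."""

    slope: float = 0.9
    intercept: float = -0.05

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")


def fraction_strong_tubulin(mix: NucleotideMix, ratio: AffinityRatio) -> float:
    """Fraction of tubulin carrying the strong nucleotide (GMPCPP).

    High-concentration limit of the competitive binding model; strictly
    decreasing in both the GDP concentration and the affinity ratio.
    """
    if mix.total == 0:
        raise ValueError("undefined composition: gmpcpp = gdp = 0")
    return mix.gmpcpp / (mix.gmpcpp + mix.gdp * ratio.r)


def fraction_strong_full(
    mix: NucleotideMix, ratio: AffinityRatio, kd_gmpcpp: float
) -> float:
    """GMPCPP-tubulin fraction from the full competitive model.

    Uses the absolute K_D^GMPCPP (uM) instead of assuming GMPCPP >> K_D;
    K_D^GDP = kd_gmpcpp / r.  Provided to check the simplification error.
    """
    if mix.total == 0:
        raise ValueError("undefined composition: gmpcpp = gdp = 0")
    kd_gdp = kd_gmpcpp / ratio.r
    return mix.gmpcpp / (mix.gmpcpp + kd_gmpcpp * (1.0 + mix.gdp / kd_gdp))


def free_gdp_fraction(frac_gdp_tubulin: float, ratio: AffinityRatio) -> float:
    """Free-nucleotide GDP mole fraction implied by a GDP-tubulin fraction.

    Inverts the competitive binding model: because tubulin binds GDP
    ``ratio``-fold more tightly than GMPCPP, the solution is depleted of GDP
    relative to the tubulin-bound pool,
    f_free = f_tub / (f_tub + (1 - f_tub) * r).  Used when nucleotide
    exchange picks a replacement from the free pool.
    """
    f = frac_gdp_tubulin
    if not 0.0 <= f <= 1.0:
        raise ValueError("frac_gdp_tubulin must be in [0, 1]")
    if f in (0.0, 1.0):
        return f
    return f / (f + (1.0 - f) * ratio.r)


def predict_minus_rate(
    gdp: float,
    ratio: AffinityRatio,
    tubulin_total: float,
    cal: MinusCalibration = MinusCalibration(),
    total_nucleotide: float = 1000.0,
) -> float:
    """Minus-end growth rate (nm/s) at a GDP concentration (uM).

    Composes the calibration line with the competitive-binding fraction:
    only GMPCPP-tubulin contributes to minus-end growth.
    """
    mix = NucleotideMix.from_gdp(gdp, total_nucleotide)
    f = fraction_strong_tubulin(mix, ratio)
    return cal.slope * tubulin_total * f + cal.intercept


@dataclass
class AffinityRatioFit:
    ratio: AffinityRatio
    stderr: float  # standard error of r from the fit covariance


def fit_affinity_ratio(
    dataset: GrowthRateDataset,
    tubulin_total: float,
    cal: MinusCalibration = MinusCalibration(),
    total_nucleotide: float = 1000.0,
) -> AffinityRatioFit:
    """Weighted fit of the affinity ratio to minus-end rates vs [GDP].

    Weights are 1/SEM per condition; conditions with n = 1 (no SEM) are
    excluded with a warning.  The single free parameter is log(r), which
    keeps r positive and well-scaled over decades; the returned standard
    error is propagated back to the r scale.

    Raises
    ------
    ValueError
        If fewer than two distinct GDP levels remain, or no GDP is present
        at all (r is then unidentifiable).
    """
    summary = dataset.summary()
    if "gdp_uM" not in summary.columns:
        raise ValueError("dataset must have a gdp_uM condition column")
    keep = summary["n"] > 1
    if (~keep).any():
        warnings.warn(
            f"excluding {int((~keep).sum())} condition(s) with n=1 (no SEM)",
            stacklevel=2,
        )
        summary = summary[keep]
    gdp = summary["gdp_uM"].to_numpy(dtype=float)
    y = summary["rate_nm_s_mean"].to_numpy(dtype=float)
    sem = summary["sem"].to_numpy(dtype=float)
    if len(np.unique(gdp)) < 2:
        raise ValueError("need >= 2 distinct GDP levels to fit the ratio")
    if np.all(gdp == 0):
        raise ValueError("all-zero GDP: affinity ratio is unidentifiable")
    sem = np.where(sem > 0, sem, np.max(sem[sem > 0]) if (sem > 0).any() else 1.0)

    def model(g, log_r):
        ratio = AffinityRatio(float(np.exp(log_r)))
        return np.array(
            [predict_minus_rate(gi, ratio, tubulin_total, cal, total_nucleotide) for gi in g]
        )

    popt, pcov = curve_fit(
        model, gdp, y, p0=[np.log(10.0)], sigma=sem, absolute_sigma=False
    )
    log_r, log_r_se = float(popt[0]), float(np.sqrt(pcov[0, 0]))
    r = float(np.exp(log_r))
    return AffinityRatioFit(ratio=AffinityRatio(r), stderr=r * log_r_se)
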