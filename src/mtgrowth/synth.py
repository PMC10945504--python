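"""Synthetic dataset generators with recorded ground truth.

Every generator is a pure function of (truth, design, seed): identical
inputs give bit-identical outputs, and the returned objects carry the truth
used so recovery tests can close the loop.

Growth-rate datasets emulate per-microtubule growth measurements: tens of
replicates per condition with large scatter (the per-kymograph variation of
slow GMPCPP growth), modelled as i.i.d. Gaussian replicates around a model-
or simulation-derived condition mean with SD = cv * |mean|, floored at
0.05 nm/s so near-zero growth conditions keep a finite spread.

Fluorescence datasets emulate plate-reader tryptophan-quench titrations:
three replicate wells per point in a tubulin channel, a BSA channel matched
for fluorescence but subject to the same inner-filter attenuation, and a
constant blank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import FluorescenceDataset, GrowthRateDataset
from .engine import SimProtocol, run_protocol
from .equilibrium import (
    AffinityRatio,
    MinusCalibration,
    NucleotideMix,
    fraction_strong_tubulin,
    free_gdp_fraction,
    predict_minus_rate,
)
from .kinetics import KineticParams, SolutionState
from .lattice import LatticeConfig

__all__ = [
    "GrowthNoiseModel",
    "AssayTruth",
    "gen_minus_mixed_dataset",
    "gen_plus_mixed_dataset",
    "gen_fluorescence_dataset",
    "gen_competition_dataset",
]

#: replicate-rate SD floor (nm/s); keeps near-zero-growth conditions finite
_RATE_SD_FLOOR = 0.05


@dataclass(frozen=True)
class GrowthNoiseModel:
    """Replicate scatter: SD = cv * |mean| (floored), n replicates/condition."""

    cv: float = 0.25
    n_per_condition: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")

    def replicate_sd(self, mean: float) -> float:
        return max(self.cv * abs(mean), _RATE_SD_FLOOR) if self.cv > 0 else 0.0


@dataclass(frozen=True)
class AssayTruth:
    """Ground truth of a synthetic fluorescence assay pair.

    K_Ds in uM; A/B on the corrected-signal scale; F magnitudes arbitrary
    units.  ``inner_filter_k`` is the attenuation constant of the titrant
    absorbance proxy applied to both tubulin and BSA channels.
    """

    KD_6T: float = 2.0
    KD_GDP: float = 0.5
    KD_GMPCPP: float = 5.0
    A: float = 0.4
    B: float = 1.0
    F_scale: float = 1000.0
    F_blank: float = 50.0
    inner_filter_k: float = 0.02  # per uM titrant
    noise_sd: float = 0.0  # well-to-well fluorescence SD (arbitrary units)

    @property
    def ratio(self) -> float:
        return self.KD_GMPCPP / self.KD_GDP


def _replicate_rows(
    means: list[tuple[dict, float]], noise: GrowthNoiseModel, condition_cols: tuple[str, ...]
) -> GrowthRateDataset:
    rng = np.random.default_rng(noise.seed)
    rows = []
    for cond, mean in means:
        sd = noise.replicate_sd(mean)
        draws = mean + sd * rng.standard_normal(noise.n_per_condition)
        for r, rate in enumerate(draws):
            rows.append({**cond, "replicate": r, "rate_nm_s": float(rate)})
    df = pd.DataFrame(rows, columns=[*condition_cols, "replicate", "rate_nm_s"])
    return GrowthRateDataset(replicates=df, condition_cols=condition_cols)


def gen_minus_mixed_dataset(
    ratio: AffinityRatio,
    gdp_levels: list[float],
    noise: GrowthNoiseModel,
    tubulin_total: float = 1.25,
    cal: MinusCalibration = MinusCalibration(),
    total_nucleotide: float = 1000.0,
) -> GrowthRateDataset:
    """Minus-end growth rates vs [GDP], means from the competitive model."""
    means = [
        (
            {"gdp_uM": float(g)},
            predict_minus_rate(g, ratio, tubulin_total, cal, total_nucleotide),
        )
        for g in gdp_levels
    ]
    return _replicate_rows(means, noise, ("gdp_uM",))


def gen_plus_mixed_dataset(
    params: KineticParams,
    gdp_fracs: list[float],
    noise: GrowthNoiseModel,
    config: LatticeConfig,
    protocol: SimProtocol,
    tubulin_total: float = 1.25,
    free_frac_gdp_of=None,
) -> GrowthRateDataset:
    """Plus-end mixed-nucleotide rates: simulated means + replicate scatter.

    Condition means come from the KMC simulator under ``params`` (mechanism
    and exchange rate included); ``gdp_fracs`` are GDP-tubulin fractions.
    ``free_frac_gdp_of`` maps those to free-nucleotide GDP mole fractions
    (default: invert the competitive model at the 12.5-fold affinity ratio).
    """
    if free_frac_gdp_of is None:
        free_frac_gdp_of = lambda f: free_gdp_fraction(f, AffinityRatio(12.5))
    means = []
    for frac in gdp_fracs:
        sol = SolutionState(
            tubulin_total=tubulin_total,
            frac_gdp_tubulin=float(frac),
            free_frac_gdp=float(free_frac_gdp_of(frac)),
        )
        res = run_protocol(config, params, sol, protocol)
        means.append(({"frac_gdp": float(frac)}, res.mean_rate))
    return _replicate_rows(means, noise, ("frac_gdp",))


def _titration_table(
    conc: np.ndarray, y_true: np.ndarray, truth: AssayTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Raw three-channel plate readings whose corrected signal is y_true."""
    atten = np.exp(-truth.inner_filter_k * conc)
    F_bsa_true = truth.F_blank + truth.F_scale * atten
    F_tub_true = truth.F_blank + (F_bsa_true - truth.F_blank) * y_true
    n_rep = 3
    rows = []
    for c, ft, fb in zip(conc, F_tub_true, F_bsa_true):
        tub = ft + truth.noise_sd * rng.standard_normal(n_rep)
        bsa = fb + truth.noise_sd * rng.standard_normal(n_rep)
        blank = truth.F_blank + truth.noise_sd * rng.standard_normal(n_rep)
        rows.append(
            {
                "conc_uM": float(c),
                "F_tub": tub.mean(),
                "F_bsa": bsa.mean(),
                "F_blank": blank.mean(),
                "sem_tub": tub.std(ddof=1) / np.sqrt(n_rep),
                "sem_bsa": bsa.std(ddof=1) / np.sqrt(n_rep),
                "sem_blank": blank.std(ddof=1) / np.sqrt(n_rep),
            }
        )
    return pd.DataFrame(rows)


def gen_fluorescence_dataset(
    truth: AssayTruth, titrant_uM: list[float], seed: int = 0
) -> FluorescenceDataset:
    """6-thio-GTP quench titration: y = B - A c/(c + KD_6T) + plate noise."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(titrant_uM, dtype=float)
    y_true = truth.B - truth.A * conc / (conc + truth.KD_6T)
    return FluorescenceDataset(table=_titration_table(conc, y_true, truth, rng))


def gen_competition_dataset(
    truth: AssayTruth,
    competitor: str,
    competitor_uM: list[float],
    fixed_6T: float = 3.0,
    seed: int = 0,
) -> FluorescenceDataset:
    """Competition titration at fixed 6-thio-GTP for GMPCPP or GDP."""
    kd_nuc = {"GMPCPP": truth.KD_GMPCPP, "GDP": truth.KD_GDP}[competitor]
    rng = np.random.default_rng(seed)
    conc = np.asarray(competitor_uM, dtype=float)
    amp = truth.A * fixed_6T / (fixed_6T + truth.KD_6T)
    C = truth.B - amp
    alpha = 1.0 + fixed_6T / truth.KD_6T
    y_true = C + amp * conc / (conc + kd_nuc * alpha)
    # inner-filter attenuation tracks the constant 6-thio-GTP, not the competitor
    atten_conc = np.full_like(conc, fixed_6T)
    return FluorescenceDataset(
        table=_titration_table(atten_conc * 0 + fixed_6T, y_true, truth, rng).assign(
            conc_uM=conc
        ),
        fixed_6T=fixed_6T,
    )
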