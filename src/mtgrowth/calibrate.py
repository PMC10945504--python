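"""Calibration of the elongation model against growth-rate data.

Three operations connect simulations to measurements:

* ``fit_growth_line`` — SEM-weighted straight line through growth rate vs
  tubulin concentration; its x-intercept is the apparent critical
  concentration and its slope, converted from nm/s to dimers/s via the
  13/8 dimers-per-nm factor, is the apparent per-microtubule on-rate
  constant.
* ``fit_kon_end`` — simulation-based refinement of an end-specific on-rate
  constant: with the interaction affinities held fixed, find the k_on whose
  simulated concentration series best matches target rates (SEM-weighted
  squared error).  Every candidate k_on is evaluated with the same replicate
  seeds (common random numbers), which makes the noisy objective effectively
  smooth in k_on; the search is a coarse log-grid followed by golden-section
  refinement.
* ``scan_exchange_rate`` — full simulation of a plus-end mixed-nucleotide
  series at each candidate nucleotide-exchange rate, reporting the SSE
  profile and its argmin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import GrowthRateDataset
from .engine import SimProtocol, run_protocol
from .kinetics import KineticParams, SolutionState
from .lattice import LatticeConfig

__all__ = [
    "LineFit",
    "fit_growth_line",
    "fit_kon_end",
    "scan_exchange_rate",
]

#: dimers per nm of mean length for the canonical lattice (13 PF / 8 nm)
_DIMERS_PER_NM = 13.0 / 8.0


@dataclass(frozen=True)
class LineFit:
    """Growth rate vs concentration line and its derived biochemical numbers.

    ``Cc_app`` (uM) is the x-intercept (net growth = 0); ``kon_app``
    (uM^-1 s^-1 per microtubule) is the slope expressed in dimers/s.  The
    conversion assumes the canonical 13-protofilament, 8-nm-dimer lattice.
    """

    slope: float
    intercept: float

    @property
    def Cc_app(self) -> float:
        return -self.intercept / self.slope

    @property
    def kon_app(self) -> float:
        return self.slope * _DIMERS_PER_NM

    def predict(self, conc):
        return self.slope * np.asarray(conc, dtype=float) + self.intercept


def fit_growth_line(dataset: GrowthRateDataset) -> LineFit:
    """SEM-weighted least-squares line through rate vs tubulin concentration.

    Equal (or all-zero) SEMs reduce to ordinary least squares.
    """
    summary = dataset.summary()
    if "tubulin_uM" not in summary.columns:
        raise ValueError("dataset must have a tubulin_uM condition column")
    if len(summary) < 2:
        raise ValueError("need >= 2 concentrations to fit a line")
    x = summary["tubulin_uM"].to_numpy(dtype=float)
    y = summary["rate_nm_s_mean"].to_numpy(dtype=float)
    sem = summary["sem"].to_numpy(dtype=float)
    if np.all(sem <= 0):
        w = np.ones_like(sem)
    else:
        w = 1.0 / np.maximum(sem, sem[sem > 0].min()) ** 2
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    slope = np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2)
    intercept = ym - slope * xm
    return LineFit(slope=float(slope), intercept=float(intercept))


def _objective(
    kon: float,
    conc: np.ndarray,
    target: np.ndarray,
    weight: np.ndarray,
    params: KineticParams,
    end: str,
    config: LatticeConfig,
    protocol: SimProtocol,
) -> float:
    from dataclasses import replace

    p = replace(params, kon_plus=kon) if end == "plus" else replace(params, kon_minus=kon)
    sse = 0.0
    for c, t, w in zip(conc, target, weight):
        res = run_protocol(config, p, SolutionState(tubulin_total=c), protocol)
        sse += w * (res.mean_rate - t) ** 2
    return sse


def fit_kon_end(
    conc: np.ndarray,
    target_rates: np.ndarray,
    params: KineticParams,
    config: LatticeConfig,
    protocol: SimProtocol,
    sems: np.ndarray | None = None,
    bracket: tuple[float, float] = (0.05, 5.0),
    n_grid: int = 8,
    rel_tol: float = 0.01,
) -> float:
    """Fit the end-specific on-rate constant to target growth rates.

    Parameters
    ----------
    conc, target_rates, sems
        Concentration grid (uM), target mean rates (nm/s) and optional
        per-condition SEMs (weights 1/SEM; equal weights when omitted).
    params, config, protocol
        Fixed affinities / lattice / replicate protocol.  ``config.polarity``
        selects which on-rate constant is fitted.  All evaluations share
        ``protocol.base_seed`` (common random numbers).
    bracket, n_grid, rel_tol
        Log-spaced coarse grid over ``bracket`` followed by golden-section
        refinement to a relative tolerance in k_on.

    Raises
    ------
    ValueError
        If the coarse-grid minimum lands on the bracket edge (the bracket
        does not contain the optimum) or the grid profile is not unimodal.
    """
    conc = np.asarray(conc, dtype=float)
    target_rates = np.asarray(target_rates, dtype=float)
    if sems is None or np.all(np.asarray(sems) <= 0):
        weight = np.ones_like(target_rates)
    else:
        sems = np.asarray(sems, dtype=float)
        weight = 1.0 / np.maximum(sems, sems[sems > 0].min()) ** 2
    end = config.polarity

    def f(kon: float) -> float:
        return _objective(kon, conc, target_rates, weight, params, end, config, protocol)

    grid = np.geomspace(bracket[0], bracket[1], n_grid)
    vals = np.array([f(k) for k in grid])
    i = int(np.argmin(vals))
    if i in (0, n_grid - 1):
        raise ValueError(
            f"objective minimized at bracket edge (kon={grid[i]:.3g}); "
            "widen the search range"
        )
    # unimodality diagnostic on the coarse profile
    d = np.sign(np.diff(vals))
    if np.count_nonzero(np.diff(d[d != 0])) > 1:
        raise ValueError("objective is not unimodal over the grid; cannot bracket")

    lo, hi = grid[i - 1], grid[i + 1]
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    # golden section on log(kon)
    a, b = math.log(lo), math.log(hi)
    c = b - phi * (b - a)
    d_ = a + phi * (b - a)
    fc, fd = f(math.exp(c)), f(math.exp(d_))
    while (b - a) > rel_tol:
        if fc < fd:
            b, d_, fd = d_, c, fc
            c = b - phi * (b - a)
            fc = f(math.exp(c))
        else:
            a, c, fc = c, d_, fd
            d_ = a + phi * (b - a)
            fd = f(math.exp(d_))
    return float(math.exp((a + b) / 2.0))


def scan_exchange_rate(
    gdp_fracs: np.ndarray,
    target_rates: np.ndarray,
    params: KineticParams,
    config: LatticeConfig,
    protocol: SimProtocol,
    k_ex_grid: np.ndarray,
    tubulin_total: float,
    free_frac_gdp_of: "callable | None" = None,
    sems: np.ndarray | None = None,
) -> pd.DataFrame:
    """SSE of simulated plus-end mixed-nucleotide rates over an exchange grid.

    For each exchange rate in ``k_ex_grid`` the full condition series is
    simulated (``gdp_fracs`` are GDP-tubulin fractions; ``free_frac_gdp_of``
    maps a tubulin fraction to the free-nucleotide GDP mole fraction and
    defaults to inverting the competitive binding model with the 12.5-fold
    affinity ratio).  Returns a tidy frame with one row per
    (k_ex, condition) carrying the simulated mean rate, plus per-k_ex SSE;
    the argmin row set has ``is_best = True``.
    """
    k_ex_grid = np.asarray(k_ex_grid, dtype=float)
    if k_ex_grid.size == 0:
        raise ValueError("empty exchange-rate grid")
    gdp_fracs = np.asarray(gdp_fracs, dtype=float)
    target_rates = np.asarray(target_rates, dtype=float)
    if sems is None or np.all(np.asarray(sems) <= 0):
        weight = np.ones_like(target_rates)
    else:
        sems = np.asarray(sems, dtype=float)
        weight = 1.0 / np.maximum(sems, sems[sems > 0].min()) ** 2
    if free_frac_gdp_of is None:
        from .equilibrium import AffinityRatio, free_gdp_fraction

        free_frac_gdp_of = lambda f: free_gdp_fraction(f, AffinityRatio(12.5))

    from dataclasses import replace

    rows = []
    sse = []
    for k_ex in k_ex_grid:
        p = replace(params, k_exchange_gdp=float(k_ex))
        err = 0.0
        for frac, t, w in zip(gdp_fracs, target_rates, weight):
            sol = SolutionState(
                tubulin_total=tubulin_total,
                frac_gdp_tubulin=float(frac),
                free_frac_gdp=float(free_frac_gdp_of(frac)),
            )
            res = run_protocol(config, p, sol, protocol)
            err += w * (res.mean_rate - t) ** 2
            rows.append(
                {
                    "k_ex": float(k_ex),
                    "frac_gdp": float(frac),
                    "rate_nm_s": res.mean_rate,
                    "target_nm_s": float(t),
                }
            )
        sse.append(err)
    df = pd.DataFrame(rows)
    sse_by_kex = dict(zip(k_ex_grid, sse))
    df["sse"] = df["k_ex"].map(sse_by_kex)
    best = float(k_ex_grid[int(np.argmin(sse))])
    df["is_best"] = df["k_ex"] == best
    return df
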