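"""Gillespie-type kinetic Monte Carlo engine for microtubule end elongation.

The simulation advances one reaction at a time — association of a tubulin
dimer onto a protofilament tip, dissociation of a terminal subunit, or
nucleotide exchange at an exposed plus-end terminal — producing a
"biochemical movie" of polymerization.  Event sampling uses the classic
direct method: a single exponential clock over the summed rate, then a
categorical draw proportional to the per-event rates.

Candidate sites are the single vacant site atop each protofilament (no
internal vacancies, no lateral-only additions).  Locked basal seed subunits
never dissociate, so columns never empty.  Mean length is reported in nm
relative to the seed top: each dimer advances the 13-protofilament mean by
dimer_length / n_protofilaments.

The hot loop works on flat integer/float arrays for speed, but derives its
neighbor tables from :func:`mtgrowth.lattice.lateral_bonds` and its rate
tables from :func:`mtgrowth.kinetics.site_KD`, so the event rates are by
construction the ones those module surfaces define.  Internally only the
strength class of each bound nucleotide is tracked (strong vs GDP);
snapshots report strong subunits as the solution's strong species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datasets import GrowthRateDataset
from .kinetics import (
    INTERFACE_ACTING,
    KineticParams,
    SolutionState,
    site_KD,
)
from .lattice import (
    GDP,
    ContactClass,
    LatticeConfig,
    LatticeState,
    Subunit,
    lateral_bonds,
)

__all__ = [
    "SimProtocol",
    "Trace",
    "GrowthResult",
    "Simulation",
    "simulate_trace",
    "estimate_growth_rate",
    "run_protocol",
    "scan",
]

ASSOCIATION = "association"
DISSOCIATION = "dissociation"
EXCHANGE = "exchange"

_STRONG, _WEAK = 0, 1


@dataclass(frozen=True)
class SimProtocol:
    """Replicate protocol: ``n_replicates`` runs of ``duration`` seconds.

    Replicate ``r`` uses seed ``base_seed + r``, so a protocol is exactly
    reproducible and two ends / mechanisms can share random numbers by
    sharing ``base_seed``.
    """

    duration: float = 600.0
    n_replicates: int = 50
    base_seed: int = 0
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")


@dataclass
class Trace:
    """Mean length (nm, relative to seed top) sampled on a regular grid."""

    times: np.ndarray
    mean_length_nm: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class GrowthResult:
    """Per-replicate growth rates with their mean and SD (nm/s)."""

    rates: np.ndarray
    mean_rate: float
    sd_rate: float
    n: int


class Simulation:
    """Mutable KMC simulation of one microtubule end.

    Parameters
    ----------
    config, params, sol
        Lattice geometry, kinetic parameters and reservoir composition.
    rng
        Seed or ``numpy.random.Generator``. All stochastic choices (waiting
        times, event selection, incoming/replacement nucleotides) draw from
        this single stream, so a seed fixes the full trajectory.
    state
        Optional starting :class:`LatticeState`; defaults to a blunt seed.
    """

    def __init__(
        self,
        config: LatticeConfig,
        params: KineticParams,
        sol: SolutionState,
        rng: int | np.random.Generator = 0,
        state: LatticeState | None = None,
    ):
        self.config = config
        self.params = params
        self.sol = sol
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.time = 0.0
        self.n_events = {ASSOCIATION: 0, DISSOCIATION: 0, EXCHANGE: 0}

        n = config.n_protofilaments
        if state is None:
            self._heights = [config.seed_rows] * n
            self._nuc = [[_STRONG] * config.seed_rows for _ in range(n)]
        else:
            if state.config.n_protofilaments != n:
                raise ValueError("state does not match config")
            self._heights = [len(col) for col in state.columns]
            self._nuc = [
                [_WEAK if s.nucleotide == GDP else _STRONG for s in col]
                for col in state.columns
            ]
            self.time = state.sim_time

        # neighbor tables (pf -> ((q, row_offset, 2*weight), ...)), derived
        # from the lattice module so seam handling cannot drift between modules
        ref_row = 10_000
        self._nbr = tuple(
            tuple(
                (q, r - ref_row, int(2 * w))
                for q, r, w in lateral_bonds(config, pf, ref_row, config.polarity)
            )
            for pf in range(n)
        )

        # rate tables: koff[strength][2 * lateral bonds], exchange[strength]
        kon = params.kon_end(config.polarity)
        nuc_of = {_STRONG: sol.strong_species, _WEAK: GDP}
        self._koff = tuple(
            tuple(
                kon * site_KD(ContactClass(b2 / 2), nuc_of[w], params)
                for b2 in range(5)
            )
            for w in (_STRONG, _WEAK)
        )
        if config.polarity == "plus" and params.k_exchange_gdp > 0:
            self._kex = (
                params.exchange_ratio * params.k_exchange_gdp,
                params.k_exchange_gdp,
            )
        else:
            self._kex = (0.0, 0.0)
        self._kon_c = kon * sol.tubulin_total

        # per-protofilament channel rates [association, dissociation, exchange]
        self._rates = [[0.0, 0.0, 0.0] for _ in range(n)]
        for pf in range(n):
            self._update_pf(pf)

    # -- rate bookkeeping ----------------------------------------------------

    def _update_pf(self, pf: int) -> None:
        h = self._heights[pf]
        col = self._nuc[pf]
        cfg = self.config
        r = self._rates[pf]
        r[0] = (
            0.0
            if (cfg.max_rows is not None and h >= cfg.max_rows)
            else self._kon_c
        )
        if h == 1:  # terminal is the locked seed base
            r[1] = 0.0
            r[2] = 0.0
            return
        row = h - 1
        b2 = 0  # lateral bonds in half-bond units
        heights = self._heights
        for q, dr, w2 in self._nbr[pf]:
            rr = row + dr
            if 0 <= rr < heights[q]:
                b2 += w2
        if cfg.polarity == "plus" and self.params.mechanism == INTERFACE_ACTING:
            governing = col[h - 2]
        else:
            governing = col[h - 1]
        r[1] = self._koff[governing][b2]
        r[2] = self._kex[col[h - 1]]

    def total_rate(self) -> float:
        return sum(a + b + c for a, b, c in self._rates)

    def rates_table(self) -> list[tuple[float, float, float]]:
        """Per-protofilament (association, dissociation, exchange) rates."""
        return [tuple(r) for r in self._rates]

    # -- state access --------------------------------------------------------

    def heights(self) -> list[int]:
        return list(self._heights)

    def mean_length_nm(self) -> float:
        cfg = self.config
        extra = sum(self._heights) - cfg.n_protofilaments * cfg.seed_rows
        return extra / cfg.n_protofilaments * cfg.dimer_length_nm

    def snapshot(self) -> LatticeState:
        """Current state as a :class:`LatticeState` (strong -> strong species)."""
        strong = self.sol.strong_species
        cols = [
            [
                Subunit(GDP if w == _WEAK else strong, locked=(row == 0))
                for row, w in enumerate(col)
            ]
            for col in self._nuc
        ]
        return LatticeState(config=self.config, columns=cols, sim_time=self.time)

    # -- stepping ------------------------------------------------------------

    def step(self) -> tuple[tuple[str, int] | None, float]:
        """Execute one reaction; return ((event_kind, pf), dt).

        When the total rate is zero (fully eroded lattice with no free
        tubulin) there is no next event: returns ``(None, inf)`` as a stall
        signal and leaves the state untouched.
        """
        total = self.total_rate()
        if total <= 0.0:
            return None, math.inf
        rng = self.rng
        dt = -math.log(1.0 - rng.random()) / total
        event = self._select(rng.random() * total)
        self._apply(event)
        self.time += dt
        return event, dt

    def _select(self, target: float) -> tuple[str, int]:
        last = None
        for pf, (ra, rd, re) in enumerate(self._rates):
            if ra > 0.0:
                last = (ASSOCIATION, pf)
                if target < ra:
                    return last
                target -= ra
            if rd > 0.0:
                last = (DISSOCIATION, pf)
                if target < rd:
                    return last
                target -= rd
            if re > 0.0:
                last = (EXCHANGE, pf)
                if target < re:
                    return last
                target -= re
        assert last is not None  # float residue: fall back to last channel
        return last

    def _apply(self, event: tuple[str, int]) -> None:
        kind, pf = event
        if kind == ASSOCIATION:
            w = _WEAK if self.rng.random() < self.sol.frac_gdp_tubulin else _STRONG
            self._nuc[pf].append(w)
            self._heights[pf] += 1
        elif kind == DISSOCIATION:
            self._nuc[pf].pop()
            self._heights[pf] -= 1
        else:  # exchange
            w = _WEAK if self.rng.random() < self.sol.free_frac_gdp else _STRONG
            self._nuc[pf][-1] = w
        self.n_events[kind] += 1
        self._update_pf(pf)
        if kind != EXCHANGE:
            for q, _, _w in self._nbr[pf]:
                self._update_pf(q)

    # -- optimized trace loop ------------------------------------------------

    def run(self, duration: float, sample_interval: float = 1.0) -> Trace:
        """Run until ``self.time`` reaches ``duration``; sample mean length.

        Samples are taken on the grid ``sample_interval * {1, 2, ...}``
        (plus the t=0 origin), each recording the state that spans the
        sample instant.
        """
        n_samples = int(math.floor(duration / sample_interval + 1e-9))
        times = np.arange(n_samples + 1, dtype=float) * sample_interval
        lengths = np.empty(n_samples + 1)
        lengths[0] = self.mean_length_nm()

        cfg = self.config
        per_dimer = cfg.dimer_length_nm / cfg.n_protofilaments
        extra = sum(self._heights) - cfg.n_protofilaments * cfg.seed_rows

        rates = self._rates
        heights = self._heights
        nuc = self._nuc
        nbr = self._nbr
        koff = self._koff
        kex = self._kex
        kon_c = self._kon_c
        max_rows = cfg.max_rows
        interface = cfg.polarity == "plus" and self.params.mechanism == INTERFACE_ACTING
        frac_gdp = self.sol.frac_gdp_tubulin
        free_gdp = self.sol.free_frac_gdp
        n_events = self.n_events
        log = math.log

        # buffered uniforms: one stream, consumed in order
        rng = self.rng
        buf = rng.random(8192)
        bi = 0
        nbuf = len(buf)

        def refill():
            nonlocal buf, bi
            buf = rng.random(8192)
            bi = 0

        pf_tot = [a + b + c for a, b, c in rates]

        def update(pf: int) -> float:
            """Refresh pf's channel rates; return the change in total rate."""
            h = heights[pf]
            r = rates[pf]
            r0 = 0.0 if (max_rows is not None and h >= max_rows) else kon_c
            if h == 1:
                r[0], r[1], r[2] = r0, 0.0, 0.0
                new = r0
            else:
                row = h - 1
                b2 = 0
                for q, dr, w2 in nbr[pf]:
                    rr = row + dr
                    if 0 <= rr < heights[q]:
                        b2 += w2
                col = nuc[pf]
                governing = col[h - 2] if interface else col[h - 1]
                r1 = koff[governing][b2]
                r2 = kex[col[h - 1]]
                r[0], r[1], r[2] = r0, r1, r2
                new = r0 + r1 + r2
            delta = new - pf_tot[pf]
            pf_tot[pf] = new
            return delta

        t = self.time
        isample = 1
        resync = 0
        total = sum(pf_tot)
        while isample <= n_samples:
            if total <= 1e-12:
                # stall: no possible event, advance through remaining samples
                length = extra * per_dimer
                while isample <= n_samples:
                    lengths[isample] = length
                    isample += 1
                t = duration
                break
            if bi >= nbuf - 3:
                refill()
            u = buf[bi]
            bi += 1
            t_new = t - log(1.0 - u) / total
            while isample <= n_samples and times[isample] <= t_new:
                lengths[isample] = extra * per_dimer
                isample += 1
            if isample > n_samples:
                t = t_new
                break
            # select event
            target = buf[bi] * total
            bi += 1
            pf = -1
            kind = -1
            for i in range(len(rates)):
                ra, rd, re = rates[i]
                if ra > 0.0:
                    pf, kind = i, 0
                    if target < ra:
                        break
                    target -= ra
                if rd > 0.0:
                    pf, kind = i, 1
                    if target < rd:
                        break
                    target -= rd
                if re > 0.0:
                    pf, kind = i, 2
                    if target < re:
                        break
                    target -= re
            # apply
            if kind == 0:
                w = _WEAK if buf[bi] < frac_gdp else _STRONG
                bi += 1
                nuc[pf].append(w)
                heights[pf] += 1
                extra += 1
                n_events[ASSOCIATION] += 1
            elif kind == 1:
                nuc[pf].pop()
                heights[pf] -= 1
                extra -= 1
                n_events[DISSOCIATION] += 1
            else:
                w = _WEAK if buf[bi] < free_gdp else _STRONG
                bi += 1
                nuc[pf][-1] = w
                n_events[EXCHANGE] += 1
            total += update(pf)
            if kind != 2:
                for q, _, _w in nbr[pf]:
                    total += update(q)
            t = t_new
            resync += 1
            if resync >= 4096:  # periodic re-sum kills float drift
                total = sum(pf_tot)
                resync = 0

        self.time = max(t, duration)
        return Trace(times=times, mean_length_nm=lengths)


def simulate_trace(
    config: LatticeConfig,
    params: KineticParams,
    sol: SolutionState,
    duration: float,
    seed: int,
    sample_interval: float = 1.0,
) -> Trace:
    """One KMC trajectory from a blunt seed, sampled every ``sample_interval`` s."""
    sim = Simulation(config, params, sol, rng=seed)
    return sim.run(duration, sample_interval)


def estimate_growth_rate(trace: Trace) -> float:
    """Growth rate (nm/s) as the OLS slope of mean length vs time."""
    if len(trace.times) < 2:
        raise ValueError("need at least 2 samples to estimate a growth rate")
    t = trace.times
    y = trace.mean_length_nm
    tm = t.mean()
    return float(((t - tm) @ (y - y.mean())) / ((t - tm) @ (t - tm)))


def run_protocol(
    config: LatticeConfig,
    params: KineticParams,
    sol: SolutionState,
    protocol: SimProtocol,
) -> GrowthResult:
    """Replicate growth rates: ``n_replicates`` independent traces.

    Replicate ``r`` is seeded with ``base_seed + r``; the SD is the ddof=1
    sample standard deviation (0 by convention for a single replicate).
    """
    rates = np.empty(protocol.n_replicates)
    for r in range(protocol.n_replicates):
        trace = simulate_trace(
            config,
            params,
            sol,
            protocol.duration,
            protocol.base_seed + r,
            protocol.sample_interval,
        )
        rates[r] = estimate_growth_rate(trace)
    sd = float(rates.std(ddof=1)) if protocol.n_replicates > 1 else 0.0
    return GrowthResult(
        rates=rates,
        mean_rate=float(rates.mean()),
        sd_rate=sd,
        n=protocol.n_replicates,
    )


def scan(
    config: LatticeConfig,
    params: KineticParams,
    protocol: SimProtocol,
    conditions: list[SolutionState],
) -> GrowthRateDataset:
    """Run the protocol over a list of solution conditions.

    Every condition reuses the same replicate seeds (``base_seed + r``), so
    two scans that share a protocol also share random numbers — e.g. the
    minus-end tables under the two mechanism modes are then identical, not
    merely statistically equivalent.
    """
    import pandas as pd

    rows = []
    for sol in conditions:
        result = run_protocol(config, params, sol, protocol)
        for r, rate in enumerate(result.rates):
            rows.append(
                {
                    "tubulin_uM": sol.tubulin_total,
                    "frac_gdp": sol.frac_gdp_tubulin,
                    "replicate": r,
                    "rate_nm_s": rate,
                }
            )
    df = pd.DataFrame(
        rows, columns=["tubulin_uM", "frac_gdp", "replicate", "rate_nm_s"]
    )
    return GrowthRateDataset(replicates=df, condition_cols=("tubulin_uM", "frac_gdp"))
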