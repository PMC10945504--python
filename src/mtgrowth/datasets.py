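"""Tabular containers shared by the simulator, generators and fits."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GrowthRateDataset", "FluorescenceDataset"]


@dataclass
class GrowthRateDataset:
    """Per-replicate growth rates grouped by experimental condition.

    ``replicates`` holds one row per individual growth-rate measurement with
    the condition columns (e.g. ``tubulin_uM``, ``gdp_uM`` or ``frac_gdp``),
    a ``replicate`` index and ``rate_nm_s``.  ``summary()`` reduces to one
    row per condition with mean, SD, SEM (= SD/sqrt(n)) and n.
    """

    replicates: pd.DataFrame
    condition_cols: tuple[str, ...]

    REQUIRED = ("replicate", "rate_nm_s")

    def __post_init__(self) -> None:
        missing = [
            c
            for c in (*self.condition_cols, *self.REQUIRED)
            if c not in self.replicates.columns
        ]
        if missing:
            raise ValueError(f"replicate table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.replicates)

    def summary(self) -> pd.DataFrame:
        if self.replicates.empty:
            cols = [*self.condition_cols, "rate_nm_s_mean", "sd", "sem", "n"]
            return pd.DataFrame(columns=cols)
        g = self.replicates.groupby(list(self.condition_cols), sort=True)["rate_nm_s"]
        out = g.agg(
            rate_nm_s_mean="mean",
            sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
            n="count",
        ).reset_index()
        out["sem"] = out["sd"] / np.sqrt(out["n"])
        return out[[*self.condition_cols, "rate_nm_s_mean", "sd", "sem", "n"]]

    # -- CSV round-trip ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.replicates.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, condition_cols: tuple[str, ...]) -> "GrowthRateDataset":
        df = pd.read_csv(path)
        return cls(replicates=df, condition_cols=tuple(condition_cols))


@dataclass
class FluorescenceDataset:
    """A tryptophan-fluorescence titration series.

    One row per titrant concentration with the mean tubulin, BSA and blank
    channel readings and their per-point SEMs.  ``fixed_6T`` is the constant
    6-thio-GTP concentration of a competition run (NaN for the primary
    quench isotherm, where the 6-thio-GTP itself is the titrant).
    """

    table: pd.DataFrame
    fixed_6T: float = float("nan")

    REQUIRED = (
        "conc_uM",
        "F_tub",
        "F_bsa",
        "F_blank",
        "sem_tub",
        "sem_bsa",
        "sem_blank",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"fluorescence table missing columns: {missing}")
        if (self.table["conc_uM"] < 0).any():
            raise ValueError("titrant concentrations must be >= 0")
        if ((self.table["F_bsa"] - self.table["F_blank"]) <= 0).any():
            raise ValueError("F_bsa - F_blank must be > 0 at every point")

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fixed_6T: float = float("nan")) -> "FluorescenceDataset":
        return cls(table=pd.read_csv(path), fixed_6T=fixed_6T)
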