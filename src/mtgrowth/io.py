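"""Configuration and file I/O: CSV datasets, parameter files, run configs.

CSV is the canonical tabular format and JSON/YAML the config format; all
artifacts are plain text and diff-able.  A saved :class:`RunConfig`
reproduces a run bit-for-bit for the same code version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .datasets import GrowthRateDataset
from .engine import SimProtocol
from .kinetics import KineticParams
from .lattice import LatticeConfig

__all__ = [
    "RunConfig",
    "read_growth_csv",
    "write_growth_csv",
    "read_params",
    "write_params",
    "run_logger",
]

log = logging.getLogger("mtgrowth")


def write_growth_csv(dataset: GrowthRateDataset, path: str | Path) -> None:
    dataset.to_csv(path)


def read_growth_csv(
    path: str | Path, condition_cols: tuple[str, ...]
) -> GrowthRateDataset:
    """Read a replicate-level growth CSV, validating the schema.

    Raises a parse error naming the missing column or the offending rows.
    """
    df = pd.read_csv(path)
    required = [*condition_cols, "replicate", "rate_nm_s"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = df.index[df[required].isna().any(axis=1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-basing
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    return GrowthRateDataset(replicates=df, condition_cols=tuple(condition_cols))


def write_params(params: KineticParams, path: str | Path) -> None:
    """Parameter file (JSON or YAML by extension), keys as in KineticParams."""
    path = Path(path)
    doc = params.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2) + "\n")


def read_params(path: str | Path) -> KineticParams:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: parameter file must be a mapping")
    try:
        return KineticParams.from_dict(doc)
    except TypeError as e:
        raise ValueError(f"{path}: bad parameter file ({e})") from e


@dataclass
class RunConfig:
    """Everything needed to replay a run exactly."""

    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    params: KineticParams = field(default_factory=KineticParams)
    protocol: SimProtocol = field(default_factory=SimProtocol)
    conditions: list[dict] = field(default_factory=list)
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "lattice": asdict(self.lattice),
            "params": self.params.to_dict(),
            "protocol": asdict(self.protocol),
            "conditions": self.conditions,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        return cls(
            lattice=LatticeConfig(**doc.get("lattice", {})),
            params=KineticParams.from_dict(doc.get("params", {})),
            protocol=SimProtocol(**doc.get("protocol", {})),
            conditions=list(doc.get("conditions", [])),
            seed=int(doc.get("seed", 0)),
            out_dir=doc.get("out_dir", "results"),
            log_level=doc.get("log_level", "INFO"),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(doc)

    def digest(self) -> str:
        """Stable hash of the config, for replay logging."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_logger(config: RunConfig) -> logging.Logger:
    """Logger announcing version, config hash and seed (exact-replay record)."""
    from . import __version__

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log.info(
        "mtgrowth %s | config %s | base seed %d", __version__, config.digest(), config.seed
    )
    return log
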