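"""Microtubule end lattice: geometry, occupancy and site classification.

The microtubule is modelled as ``n_protofilaments`` head-to-tail columns of
alpha/beta-tubulin dimers arranged as a B-lattice with a single seam.  A
simulation instance models exactly one end (plus or minus); the other end is
inert.  Columns are contiguous stacks of subunits (no internal vacancies):
row 0 is the seed base, rows count outward toward the growing tip, and
"terminal" always means farthest from the seed regardless of polarity.

Lateral contacts pair subunits in the same row, except across the seam where
the helical pitch breaks the registry: the pairing there is offset by
``seam_offset_rows`` dimer rows, with the sign of the offset mirrored between
plus- and minus-end polarity (the lattice looks upside-down from the other
end).  The 3-start helix of a 13-protofilament lattice concentrates a
1.5-dimer axial mismatch at the seam, so the default offset is the
half-integer 1.5: a seam subunit then half-overlaps *two* partners on the
far side, each contributing half a lateral bond (free-energy additivity).
Integer offsets give the familiar single full-strength seam partner.  The
offset is configuration, not a hard-coded truth, so its effect can be probed.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import math

__all__ = [
    "GTP",
    "GMPCPP",
    "GDP",
    "STRENGTH_CLASS",
    "is_weak",
    "LatticeConfig",
    "Subunit",
    "LatticeState",
    "ContactClass",
    "tip_row",
    "lateral_bonds",
    "lateral_neighbors",
    "classify_site",
    "interfacial_nucleotide",
    "exchange_eligible",
]

# Nucleotide species of the exchangeable (beta-tubulin) site.  GTP and its
# slowly-hydrolyzable analog GMPCPP make strong lattice contacts; GDP makes
# weak ones.  The mapping is total and fixed.
GTP = "GTP"
GMPCPP = "GMPCPP"
GDP = "GDP"

STRENGTH_CLASS = {GTP: "strong", GMPCPP: "strong", GDP: "weak"}

#: single-letter codes used in JSON snapshots
_NUC_CODE = {GTP: "T", GMPCPP: "C", GDP: "D"}
_CODE_NUC = {v: k for k, v in _NUC_CODE.items()}


def is_weak(nucleotide: str) -> bool:
    return STRENGTH_CLASS[nucleotide] == "weak"


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry of the simulated end.

    Parameters
    ----------
    n_protofilaments
        Number of protofilament columns (13 for the canonical lattice).
    dimer_length_nm
        Axial length of one tubulin dimer; converts subunit counts to nm.
    seam_offset_rows
        Axial offset, in dimer rows, of the lateral pairing across the seam;
        a multiple of 0.5.  The default 1.5 matches the helical mismatch of
        a 13-protofilament B-lattice and pairs each seam subunit with two
        half-weight partners; integer values give one full-weight partner.
    seed_rows
        Depth of the pre-built GMPCPP seed. The basal row is locked (never
        dissociates); the depth is chosen so growth never erodes to the lock.
    polarity
        "plus" (beta-tubulin interface exposed, exchangeable nucleotide
        accessible) or "minus" (alpha interface exposed, no nucleotide).
    max_rows
        Optional hard cap on column height (association disabled at the cap).
        Used for finite-state-space validation against master-equation
        integration; ``None`` (unbounded) for production runs.
    """

    n_protofilaments: int = 13
    dimer_length_nm: float = 8.0
    seam_offset_rows: float = 1.5
    seed_rows: int = 6
    polarity: str = "plus"
    max_rows: int | None = None

    def __post_init__(self) -> None:
        if self.n_protofilaments < 1:
            raise ValueError("n_protofilaments must be >= 1")
        if self.dimer_length_nm <= 0:
            raise ValueError("dimer_length_nm must be > 0")
        if self.seam_offset_rows < 0 or (2 * self.seam_offset_rows) % 1 != 0:
            raise ValueError("seam_offset_rows must be a non-negative multiple of 0.5")
        if self.seed_rows < 1:
            raise ValueError("seed_rows must be >= 1")
        if self.polarity not in ("plus", "minus"):
            raise ValueError(f"polarity must be 'plus' or 'minus', got {self.polarity!r}")
        if self.max_rows is not None and self.max_rows < self.seed_rows:
            raise ValueError("max_rows must be >= seed_rows")


@dataclass
class Subunit:
    """One tubulin dimer: its exchangeable nucleotide and a seed lock flag."""

    nucleotide: str = GMPCPP
    locked: bool = False


@dataclass
class LatticeState:
    """Occupancy and per-subunit nucleotide of one microtubule end.

    ``columns[pf]`` is the ordered stack of subunits of protofilament ``pf``
    (row 0 = seed base, growing outward).  Column contiguity (no internal
    vacancy) and a never-empty column (the locked base) are invariants that
    every event preserves.
    """

    config: LatticeConfig
    columns: list[list[Subunit]]
    sim_time: float = 0.0

    @classmethod
    def blunt_seed(cls, config: LatticeConfig) -> "LatticeState":
        """A fresh blunt GMPCPP seed of ``seed_rows`` complete rows."""
        cols = [
            [Subunit(GMPCPP, locked=(row == 0)) for row in range(config.seed_rows)]
            for _ in range(config.n_protofilaments)
        ]
        return cls(config=config, columns=cols)

    @property
    def polarity(self) -> str:
        return self.config.polarity

    def heights(self) -> list[int]:
        return [len(col) for col in self.columns]

    def occupied(self, pf: int, row: int) -> bool:
        return 0 <= row < len(self.columns[pf])

    def mean_length_nm(self) -> float:
        """Mean length over protofilaments, in nm, relative to the seed top.

        Each added dimer advances the mean by dimer_length / n_protofilaments
        (8/13 nm for the canonical lattice).
        """
        cfg = self.config
        extra = sum(len(col) - cfg.seed_rows for col in self.columns)
        return extra / cfg.n_protofilaments * cfg.dimer_length_nm

    # -- serialization (debugging / fixtures) --------------------------------

    def to_json(self) -> str:
        doc = {
            "polarity": self.polarity,
            "sim_time": self.sim_time,
            "seed_rows": self.config.seed_rows,
            "seam_offset_rows": self.config.seam_offset_rows,
            "columns": [
                "".join(_NUC_CODE[s.nucleotide] for s in col) for col in self.columns
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "LatticeState":
        doc = json.loads(text)
        config = LatticeConfig(
            n_protofilaments=len(doc["columns"]),
            seam_offset_rows=doc.get("seam_offset_rows", 2),
            seed_rows=doc.get("seed_rows", 6),
            polarity=doc["polarity"],
        )
        cols = [
            [
                Subunit(_CODE_NUC[ch], locked=(row == 0))
                for row, ch in enumerate(colstr)
            ]
            for colstr in doc["columns"]
        ]
        return cls(config=config, columns=cols, sim_time=doc.get("sim_time", 0.0))


@dataclass(frozen=True)
class ContactClass:
    """Contacts of a terminal or candidate site.

    Every such site has exactly one longitudinal contact (the subunit, or
    seed, beneath it); ``n_lateral`` counts occupied lateral bonds:
    0 = longitudinal-only, 1 = corner, 2 = bucket.  At a half-integer seam
    the two half-weight partners make half-integer bond counts possible
    (classified as corner-like for naming purposes).
    """

    n_lateral: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_lateral <= 2 or (2 * self.n_lateral) % 1 != 0:
            raise ValueError("n_lateral must be a multiple of 0.5 in [0, 2]")

    @property
    def value(self) -> str:
        if self.n_lateral == 0:
            return "longitudinal_only"
        if self.n_lateral == 2:
            return "bucket"
        return "corner"


def tip_row(state: LatticeState, pf: int) -> int:
    """Row index of the terminal (outermost) subunit of protofilament ``pf``."""
    return len(state.columns[pf]) - 1


def lateral_bonds(
    config: LatticeConfig, pf: int, row: int, polarity: str | None = None
) -> list[tuple[int, int, float]]:
    """Weighted lateral partner sites of ``(pf, row)``: (pf, row, weight).

    Non-seam partners sit in the same row with weight 1.  Across the seam
    the pairing is offset by ``seam_offset_rows`` (sign mirrored between
    plus- and minus-end polarity): an integer offset gives one full-weight
    partner, a half-integer offset gives two half-weight partners (the rows
    the seam subunit half-overlaps).  Self-pairs (1 protofilament) are
    dropped; duplicates (2-protofilament toys) are merged.
    """
    n = config.n_protofilaments
    if polarity is None:
        polarity = config.polarity
    sign = 1 if polarity == "plus" else -1
    offset = sign * config.seam_offset_rows

    def seam_partners(q: int, o: float) -> list[tuple[int, int, float]]:
        if o % 1 == 0:
            return [(q, row + int(o), 1.0)]
        lo = int(math.floor(o))
        return [(q, row + lo, 0.5), (q, row + lo + 1, 0.5)]

    raw: list[tuple[int, int, float]] = []
    # left neighbor: wraps through the seam from pf 0 to the last pf
    if pf > 0:
        raw.append((pf - 1, row, 1.0))
    else:
        raw.extend(seam_partners(n - 1, -offset))
    # right neighbor: wraps through the seam from the last pf to pf 0
    if pf < n - 1:
        raw.append((pf + 1, row, 1.0))
    else:
        raw.extend(seam_partners(0, offset))
    merged: dict[tuple[int, int], float] = {}
    for q, r, w in raw:
        if q == pf:  # single-protofilament lattice: no lateral partner
            continue
        merged[(q, r)] = merged.get((q, r), 0.0) + w
    return [(q, r, w) for (q, r), w in merged.items()]


def lateral_neighbors(
    config: LatticeConfig, pf: int, row: int, polarity: str | None = None
) -> list[tuple[int, int]]:
    """The lateral partner sites of ``(pf, row)`` (weights dropped)."""
    return [(q, r) for q, r, _ in lateral_bonds(config, pf, row, polarity)]


def classify_site(state: LatticeState, pf: int, row: int) -> ContactClass:
    """Contact class of the terminal subunit of ``pf`` or of the vacant
    candidate site directly beyond it.

    Raises
    ------
    ValueError
        If ``(pf, row)`` is neither the terminal subunit nor the candidate
        association site of that protofilament.
    """
    tip = tip_row(state, pf)
    if row not in (tip, tip + 1):
        raise ValueError(
            f"site ({pf}, {row}) is neither terminal (row {tip}) nor the "
            f"candidate site (row {tip + 1}) of protofilament {pf}"
        )
    bonds = sum(
        w
        for q, r, w in lateral_bonds(state.config, pf, row, state.polarity)
        if state.occupied(q, r)
    )
    return ContactClass(min(bonds, 2.0))


def interfacial_nucleotide(state: LatticeState, pf: int) -> str:
    """Nucleotide buried at the terminal dimer:dimer interface of ``pf``.

    At the plus-end the interfacial nucleotide is the one bound to the subunit
    one row beneath the terminal subunit (the terminal subunit's own
    nucleotide faces the solution).  At the minus-end the incoming subunit's
    alpha interface caps the terminal subunit's beta nucleotide, so the
    terminal subunit's own nucleotide is the interfacial one.
    """
    col = state.columns[pf]
    if state.polarity == "plus":
        return col[-2].nucleotide if len(col) >= 2 else col[-1].nucleotide
    return col[-1].nucleotide


def exchange_eligible(state: LatticeState) -> set[int]:
    """Protofilaments whose terminal subunit can undergo nucleotide exchange.

    Plus-end terminal subunits expose their exchangeable nucleotide to the
    solution; minus-end terminal subunits expose an alpha interface that
    carries no nucleotide, so the set is empty for minus polarity.  Locked
    seed subunits are excluded.
    """
    if state.polarity != "plus":
        return set()
    return {
        pf
        for pf, col in enumerate(state.columns)
        if not col[-1].locked
    }
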