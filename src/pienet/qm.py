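"""Bookkeeping for QM pair-interaction components and fractional unit charges.

No quantum computation happens here: this module validates and algebraically
combines component tables produced elsewhere (or by the synthetic generator).

Component conventions by level:

* ``MM``  — elec, vdw (force-field Coulomb and Lennard-Jones).
* ``PA``  — ES, DI, solv (partition-analysis electrostatics, dispersion and
  solvent screening; two-body terms carry no explicit charge-transfer term).
* ``FMO`` — ES, E0, CTES, DI, solv (fragment-based decomposition with the
  0-body exchange/repulsion term E0 and the charge-transfer coupling CTES).

The solute pair interaction energy is ES + DI; the solution value adds the
solvent screening (and, for FMO, the E0 and CTES terms).  Covalently linked
fragment pairs carry artificially large magnitudes (order −300 kcal/mol) and
are flagged so regressions can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEVEL_COMPONENTS",
    "PairComponentRecord",
    "UnitChargeRecord",
    "solute_pie",
    "solution_pie",
    "add_pie_columns",
    "charge_deviation",
    "per_type_functional_charge",
    "validate_component_frame",
    "read_component_csv",
    "write_component_csv",
    "read_charge_csv",
    "write_charge_csv",
]

LEVEL_COMPONENTS: Dict[str, tuple] = {
    "MM": ("elec", "vdw"),
    "PA": ("ES", "DI", "solv"),
    "FMO": ("ES", "E0", "CTES", "DI", "solv"),
}

_SOLUTE_COMPONENTS = {
    "MM": ("elec", "vdw"),
    "PA": ("ES", "DI"),
    "FMO": ("ES", "DI"),
}


@dataclass
class PairComponentRecord:
    """One (unit i, unit j, snapshot) row of interaction-energy components."""

    unit_i: int
    unit_j: int
    snapshot: int
    level: str                       # "MM" | "PA" | "FMO"
    components: Dict[str, float]
    scheme_name: str = "segment"
    is_covalent: bool = False

    def __post_init__(self):
        if self.level not in LEVEL_COMPONENTS:
            raise ValueError(f"unknown level {self.level!r}")
        expected = set(LEVEL_COMPONENTS[self.level])
        got = set(self.components)
        if got != expected:
            raise ValueError(
                f"level {self.level}: components {sorted(got)} do not match "
                f"expected {sorted(expected)}"
            )
        for name, value in self.components.items():
            if not np.isfinite(value):
                raise ValueError(f"component {name} is not finite")


@dataclass
class UnitChargeRecord:
    """Fractional (QM) charge of one unit at one snapshot, vs. its formal charge."""

    unit_id: int
    snapshot: int
    total_charge: float
    functional_charge: float
    formal_charge: int

    def __post_init__(self):
        if abs(self.total_charge - self.formal_charge) >= 0.5:
            raise ValueError(
                f"unit {self.unit_id}: total charge {self.total_charge} is more "
                f"than 0.5 e away from the formal charge {self.formal_charge}"
            )


def _components_of(record) -> Mapping[str, float]:
    if isinstance(record, PairComponentRecord):
        return record.components
    return record  # mapping-like (e.g. a DataFrame row)


def _level_of(record, level: Optional[str]) -> str:
    if isinstance(record, PairComponentRecord):
        return record.level
    if level is None:
        level = record.get("level") if hasattr(record, "get") else None
    if level is None:
        raise ValueError("level must be given for mapping-style records")
    return level


def solute_pie(record, level: Optional[str] = None) -> float:
    """Solute (unscreened) pair interaction energy: ES + DI (elec + vdw for MM)."""
    lvl = _level_of(record, level)
    comps = _components_of(record)
    try:
        return float(sum(comps[c] for c in _SOLUTE_COMPONENTS[lvl]))
    except KeyError as exc:
        raise ValueError(f"missing component {exc} for level {lvl}") from exc


def solution_pie(record, level: Optional[str] = None) -> float:
    """Pair interaction energy in solution: the sum of all level components."""
    lvl = _level_of(record, level)
    comps = _components_of(record)
    try:
        return float(sum(comps[c] for c in LEVEL_COMPONENTS[lvl]))
    except KeyError as exc:
        raise ValueError(f"missing component {exc} for level {lvl}") from exc


def add_pie_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Append 'solute' and 'solution' columns to a component frame."""
    frame = frame.copy()
    frame["solute"] = [
        solute_pie(row, level=row["level"]) for _, row in frame.iterrows()
    ]
    frame["solution"] = [
        solution_pie(row, level=row["level"]) for _, row in frame.iterrows()
    ]
    return frame


def charge_deviation(record, mode: str = "percent") -> float:
    """Deviation of the actual (fractional) unit charge from its formal charge.

    ``percent`` returns 100·|total − formal| / |formal| and is undefined for
    formally neutral units — use ``mode="absolute"`` (elementary charges) there.
    """
    total = record.total_charge if isinstance(record, UnitChargeRecord) else record["total_charge"]
    formal = record.formal_charge if isinstance(record, UnitChargeRecord) else record["formal_charge"]
    if mode == "absolute":
        return float(abs(total - formal))
    if mode != "percent":
        raise ValueError(f"unknown mode {mode!r}")
    if formal == 0:
        raise ValueError(
            "percent deviation undefined for formally neutral units; "
            "use mode='absolute'"
        )
    return float(100.0 * abs(total - formal) / abs(formal))


def per_type_functional_charge(frame: pd.DataFrame, residue_type: str,
                               label_col: str = "label",
                               value_col: str = "functional_charge") -> float:
    """Mean functional-unit charge over units of one residue type.

    ``residue_type`` is matched as the leading letter(s) of the unit label
    (e.g. "G" matches G6, G8, G10, G24).
    """
    import re

    mask = frame[label_col].map(
        lambda s: re.fullmatch(rf"{re.escape(residue_type)}\d+", str(s)) is not None
    )
    sel = frame.loc[mask, value_col]
    if sel.empty:
        raise ValueError(f"no units of type {residue_type!r}")
    return float(sel.mean())


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_COMPONENT_BASE_COLS = ["unit_i", "unit_j", "snapshot", "level", "scheme", "is_covalent"]
_ALL_COMPONENT_COLS = ("elec", "vdw", "ES", "E0", "CTES", "DI", "solv")
_CHARGE_COLS = ["unit_id", "label", "snapshot", "total_charge",
                "functional_charge", "formal_charge"]


def validate_component_frame(frame: pd.DataFrame) -> None:
    """Reject rows whose populated components mismatch their level."""
    for col in _COMPONENT_BASE_COLS:
        if col not in frame.columns:
            raise ValueError(f"component table missing column {col!r}")
    for idx, row in frame.iterrows():
        level = row["level"]
        if level not in LEVEL_COMPONENTS:
            raise ValueError(f"row {idx}: unknown level {level!r}")
        expected = set(LEVEL_COMPONENTS[level])
        for col in _ALL_COMPONENT_COLS:
            if col not in frame.columns:
                if col in expected:
                    raise ValueError(f"row {idx}: missing component column {col!r}")
                continue
            value = row[col]
            present = pd.notna(value)
            if present and col not in expected:
                raise ValueError(
                    f"row {idx}: component {col!r} populated for level {level}"
                )
            if not present and col in expected:
                raise ValueError(
                    f"row {idx}: component {col!r} missing for level {level}"
                )
            if present and not np.isfinite(value):
                raise ValueError(f"row {idx}: component {col!r} is not finite")


def write_component_csv(frame: pd.DataFrame, path) -> None:
    validate_component_frame(frame)
    cols = _COMPONENT_BASE_COLS + [c for c in _ALL_COMPONENT_COLS if c in frame.columns]
    frame[cols].to_csv(path, index=False, encoding="utf-8")


def read_component_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, encoding="utf-8")
    validate_component_frame(frame)
    return frame


def write_charge_csv(frame: pd.DataFrame, path) -> None:
    missing = set(_CHARGE_COLS) - set(frame.columns)
    if missing:
        raise ValueError(f"charge table missing columns {sorted(missing)}")
    frame[_CHARGE_COLS].to_csv(path, index=False, encoding="utf-8")


def read_charge_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, encoding="utf-8")
    missing = set(_CHARGE_COLS) - set(frame.columns)
    if missing:
        raise ValueError(f"charge table missing columns {sorted(missing)}")
    for idx, row in frame.iterrows():
        if abs(row["total_charge"] - row["formal_charge"]) >= 0.5:
            raise ValueError(
                f"row {idx} (unit {row['unit_id']}): total charge "
                f"{row['total_charge']} implausibly far from formal "
                f"{row['formal_charge']}"
            )
    return frame
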