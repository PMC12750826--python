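"""Compound identity and ionization-efficiency (IE) measurement handling.

Experimental logIE values for one compound scatter strongly across
instruments and eluents, so raw per-measurement records are aggregated
into model-ready entries: measurements of the same compound whose eluent
pH rounds to the same whole number are averaged (both the pH and the
logIE), one entry per (InChIKey, rounded pH) pair.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CompoundRecord",
    "IEMeasurement",
    "IEEntry",
    "MeasurementError",
    "round_half_away",
    "aggregate_measurements",
    "read_measurements",
    "write_entries",
    "read_entries",
]

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


@dataclass(frozen=True)
class CompoundRecord:
    """A chemical identity: InChIKey and/or SMILES, optionally a name.

    The 27-character InChIKey (14-10-1 uppercase blocks) is the join key
    used throughout the package; SMILES is required only where structures
    are turned into fingerprints.
    """

    inchikey: str | None = None
    smiles: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.inchikey and not self.smiles:
            raise ValueError("CompoundRecord needs an InChIKey or a SMILES")
        if self.inchikey is not None and not _INCHIKEY_RE.match(self.inchikey):
            raise ValueError(f"malformed InChIKey: {self.inchikey!r}")

    @property
    def key(self) -> str:
        """Identity key: the full InChIKey, falling back to the SMILES."""
        return self.inchikey if self.inchikey else f"SMILES:{self.smiles}"


@dataclass(frozen=True)
class IEMeasurement:
    """One reported logIE measurement at a given aqueous-phase pH."""

    compound: CompoundRecord
    log_ie: float
    ph: float


@dataclass(frozen=True)
class IEEntry:
    """Aggregate of all measurements of one compound at one rounded pH.

    ``ph`` and ``log_ie`` are arithmetic means over the ``n_source``
    underlying measurements; ``ph_bin`` is the integer the unrounded pH
    values rounded to.
    """

    compound: CompoundRecord
    ph: float
    log_ie: float
    ph_bin: int
    n_source: int


class MeasurementError(ValueError):
    """Raised when measurement records are invalid; lists each offender."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid measurement records:\n" + "\n".join(self.problems)
        )


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (2.5 -> 3)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def aggregate_measurements(
    measurements: Iterable[IEMeasurement],
) -> list[IEEntry]:
    """Group measurements by (compound key, rounded pH) and average them.

    Returns one :class:`IEEntry` per group, sorted by (key, ph_bin).
    Measurements lacking a finite pH or logIE raise
    :class:`MeasurementError` listing every offending record; nothing is
    dropped silently.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("no measurements to aggregate")

    problems: list[str] = []
    for i, m in enumerate(measurements):
        if not math.isfinite(m.ph):
            problems.append(f"record {i} ({m.compound.key}): non-finite pH")
        if not math.isfinite(m.log_ie):
            problems.append(f"record {i} ({m.compound.key}): non-finite logIE")
    if problems:
        raise MeasurementError(problems)

    groups: dict[tuple[str, int], list[IEMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.compound.key, round_half_away(m.ph)), []).append(m)

    entries = []
    for (key, ph_bin), group in sorted(groups.items()):
        # keep the most informative compound record (prefer one with SMILES)
        compound = next(
            (g.compound for g in group if g.compound.smiles), group[0].compound
        )
        entries.append(
            IEEntry(
                compound=compound,
                ph=sum(g.ph for g in group) / len(group),
                log_ie=sum(g.log_ie for g in group) / len(group),
                ph_bin=ph_bin,
                n_source=len(group),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# delimited-text IO


def read_measurements(path: str | Path, sep: str | None = None) -> list[IEMeasurement]:
    """Read measurements from a delimited text file.

    Requires columns ``log_ie`` and ``ph`` and at least one of
    ``inchikey``/``smiles``; the delimiter is sniffed unless given.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"log_ie", "ph"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "inchikey" not in df.columns and "smiles" not in df.columns:
        raise ValueError(f"{path}: need an 'inchikey' or 'smiles' column")

    problems, out = [], []
    for i, row in df.iterrows():
        ik = _clean(row.get("inchikey"))
        smi = _clean(row.get("smiles"))
        name = _clean(row.get("name"))
        if not ik and not smi:
            problems.append(f"row {i}: no identifier")
            continue
        try:
            compound = CompoundRecord(inchikey=ik, smiles=smi, name=name)
        except ValueError as exc:
            problems.append(f"row {i}: {exc}")
            continue
        out.append(
            IEMeasurement(compound, float(row["log_ie"]), float(row["ph"]))
        )
    if problems:
        raise MeasurementError(problems)
    return out


def _clean(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def entries_to_frame(entries: Sequence[IEEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "inchikey": [e.compound.inchikey for e in entries],
            "smiles": [e.compound.smiles for e in entries],
            "ph": [e.ph for e in entries],
            "log_ie": [e.log_ie for e in entries],
            "ph_bin": [e.ph_bin for e in entries],
            "n_source": [e.n_source for e in entries],
        }
    )


def write_entries(entries: Sequence[IEEntry], path: str | Path) -> None:
    entries_to_frame(entries).to_csv(path, index=False)


def read_entries(path: str | Path) -> list[IEEntry]:
    df = pd.read_csv(path)
    return [
        IEEntry(
            compound=CompoundRecord(
                inchikey=_clean(row.get("inchikey")),
                smiles=_clean(row.get("smiles")),
            ),
            ph=float(row["ph"]),
            log_ie=float(row["log_ie"]),
            ph_bin=int(row["ph_bin"]),
            n_source=int(row["n_source"]),
        )
        for _, row in df.iterrows()
    ]
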