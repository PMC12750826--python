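"""MS2 spectrum IO, quality filtering, and cumulative neutral losses.

Spectra come from MSP or MGF libraries (read and written through
matchms). Before entering the CNL workflow they are filtered to
positive-mode, [M+H]+ spectra with at least one fragment, resolution of
at least 5000, and a present InChIKey — spectra that cannot be tied
unambiguously to a structure are useless as training rows. The
cumulative neutral losses (CNLs) of a spectrum are the mass differences
between the precursor ion and each fragment ion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logging.getLogger("matchms").setLevel(logging.ERROR)

from matchms import Spectrum as MatchmsSpectrum  # noqa: E402
from matchms.exporting import save_as_mgf, save_as_msp  # noqa: E402
from matchms.importing import load_from_mgf, load_from_msp  # noqa: E402

__all__ = [
    "Spectrum",
    "CNLSet",
    "FilterTally",
    "normalize_adduct",
    "read_spectra",
    "write_spectra",
    "filter_spectra",
    "compute_cnls",
    "PROTON_MASS",
]

PROTON_MASS = 1.007276466

# dialect variants of the protonated-molecule adduct
_ADDUCT_ALIASES = {
    "[M+H]+": "[M+H]+",
    "[M+H]1+": "[M+H]+",
    "M+H": "[M+H]+",
    "M+H+": "[M+H]+",
    "[M+H]": "[M+H]+",
}


def normalize_adduct(adduct: str | None) -> str | None:
    if adduct is None:
        return None
    return _ADDUCT_ALIASES.get(adduct.strip(), adduct.strip())


@dataclass(frozen=True)
class Spectrum:
    """One MS2 spectrum: peak list plus the metadata the filters need."""

    precursor_mz: float | None
    peaks: tuple[tuple[float, float], ...]  # (mz, intensity), mz ascending
    adduct: str | None = None
    ionization_mode: str | None = None
    resolution: float | None = None
    inchikey: str | None = None
    source_id: str = ""

    def __post_init__(self):
        mzs = [p[0] for p in self.peaks]
        if any(m <= 0 for m in mzs) or any(p[1] < 0 for p in self.peaks):
            raise ValueError("peaks must have mz > 0 and intensity >= 0")
        if mzs != sorted(mzs):
            object.__setattr__(
                self, "peaks", tuple(sorted(self.peaks, key=lambda p: p[0]))
            )

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class CNLSet:
    """Cumulative neutral losses of one spectrum, ascending."""

    losses: tuple[float, ...]
    precursor_mz: float
    inchikey: str | None = None
    n_dropped: int = 0  # fragments heavier than the precursor (+tolerance)

    def __len__(self) -> int:
        return len(self.losses)


# ---------------------------------------------------------------------------
# IO


def _get_meta(meta: dict, *keys):
    for k in keys:
        v = meta.get(k)
        if v not in (None, ""):
            return v
    return None


def _to_float(value):
    if value is None:
        return None
    if isinstance(value, (tuple, list)):  # MGF PEPMASS is (mz, intensity)
        value = value[0]
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def read_spectra(path: str | Path) -> list[Spectrum]:
    """Read an MSP or MGF library into :class:`Spectrum` records.

    Unparseable records are skipped with a logged warning; a file with
    zero parseable records raises ``ValueError``. Missing optional
    metadata is left unset, never invented.
    """
    path = Path(path)
    loader = {".msp": load_from_msp, ".mgf": load_from_mgf}.get(
        path.suffix.lower()
    )
    if loader is None:
        raise ValueError(f"unsupported spectral format: {path.suffix!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    out: list[Spectrum] = []
    n_skipped = 0
    for i, ms in enumerate(loader(str(path), metadata_harmonization=True)):
        if ms is None:
            n_skipped += 1
            continue
        meta = ms.metadata
        try:
            out.append(
                Spectrum(
                    precursor_mz=_to_float(
                        _get_meta(meta, "precursor_mz", "precursormz", "pepmass")
                    ),
                    peaks=tuple(
                        zip(ms.peaks.mz.tolist(), ms.peaks.intensities.tolist())
                    ),
                    adduct=normalize_adduct(
                        _get_meta(meta, "adduct", "precursortype", "precursor_type")
                    ),
                    ionization_mode=_get_meta(meta, "ionmode", "ionization_mode"),
                    resolution=_to_float(_get_meta(meta, "resolution")),
                    inchikey=_get_meta(meta, "inchikey"),
                    source_id=_get_meta(meta, "compound_name", "title", "name")
                    or f"{path.name}#{i}",
                )
            )
        except (ValueError, AttributeError) as exc:
            n_skipped += 1
            logging.getLogger(__name__).warning(
                "skipping malformed record %d in %s: %s", i, path, exc
            )
    if not out:
        raise ValueError(f"{path}: no parseable spectra (skipped {n_skipped})")
    if n_skipped:
        logging.getLogger(__name__).warning(
            "%s: skipped %d malformed records", path, n_skipped
        )
    return out


def _to_matchms(s: Spectrum) -> MatchmsSpectrum:
    meta = {"compound_name": s.source_id or "spectrum"}
    if s.precursor_mz is not None:
        meta["precursor_mz"] = s.precursor_mz
    if s.adduct is not None:
        meta["adduct"] = s.adduct
    if s.ionization_mode is not None:
        meta["ionmode"] = s.ionization_mode
    if s.resolution is not None:
        meta["resolution"] = s.resolution
    if s.inchikey is not None:
        meta["inchikey"] = s.inchikey
    return MatchmsSpectrum(
        mz=np.array([p[0] for p in s.peaks], dtype=float),
        intensities=np.array([p[1] for p in s.peaks], dtype=float),
        metadata=meta,
        metadata_harmonization=False,
    )


def write_spectra(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra to MSP or MGF (by extension)."""
    path = Path(path)
    converted = [_to_matchms(s) for s in spectra]
    if path.exists():
        path.unlink()  # matchms appends
    if path.suffix.lower() == ".msp":
        save_as_msp(converted, str(path))
    elif path.suffix.lower() == ".mgf":
        save_as_mgf(converted, str(path))
    else:
        raise ValueError(f"unsupported spectral format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterTally:
    """Per-criterion rejection counts; a spectrum is tallied under the
    first criterion it fails, in the order of the fields below."""

    not_positive_mode: int = 0
    wrong_adduct: int = 0
    no_fragments: int = 0
    resolution_missing: int = 0
    resolution_too_low: int = 0
    inchikey_missing: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _passes(
    s: Spectrum, min_resolution: float, required_mode: str, required_adduct: str
) -> str | None:
    """Return the name of the first failed criterion, or None if kept."""
    if (s.ionization_mode or "").lower() != required_mode:
        return "not_positive_mode"
    if normalize_adduct(s.adduct) != required_adduct:
        return "wrong_adduct"
    if s.n_peaks < 1:
        return "no_fragments"
    if s.resolution is None:
        return "resolution_missing"
    if s.resolution < min_resolution:
        return "resolution_too_low"
    if not s.inchikey:
        return "inchikey_missing"
    return None


def filter_spectra(
    spectra: Iterable[Spectrum],
    min_resolution: float = 5000,
    required_mode: str = "positive",
    required_adduct: str = "[M+H]+",
) -> tuple[list[Spectrum], FilterTally]:
    """Quality-filter spectra; order-preserving and idempotent.

    Spectra with a missing resolution are rejected (conservative reading
    of the minimum-resolution requirement) and tallied separately.
    """
    kept: list[Spectrum] = []
    tally = FilterTally()
    for s in spectra:
        fail = _passes(s, min_resolution, required_mode.lower(), required_adduct)
        if fail is None:
            kept.append(s)
            tally.retained += 1
        else:
            setattr(tally, fail, getattr(tally, fail) + 1)
    return kept, tally


# ---------------------------------------------------------------------------
# cumulative neutral losses


def compute_cnls(spectrum: Spectrum, tol: float = 0.020) -> CNLSet:
    """Losses = precursor m/z minus each fragment m/z, ascending.

    Fragments heavier than the precursor by more than ``tol`` (isotope or
    contaminant artifacts) are dropped and counted in ``n_dropped``;
    small overshoots within tolerance clamp to a loss of 0.
    """
    if spectrum.precursor_mz is None:
        raise ValueError("spectrum has no precursor m/z")
    p = spectrum.precursor_mz
    losses, dropped = [], 0
    for mz, _ in spectrum.peaks:
        if mz <= p + tol:
            losses.append(max(p - mz, 0.0))
        else:
            dropped += 1
    return CNLSet(
        losses=tuple(sorted(losses)),
        precursor_mz=p,
        inchikey=spectrum.inchikey,
        n_dropped=dropped,
    )
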