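"""Synthetic fixtures with planted, recoverable structure.

The generator emulates the three inputs of the logIE workflows without
any download: (1) small organic compounds assembled combinatorially from
alkyl chains, amines, hydroxyls, carboxylic acids and benzene rings;
(2) their IE measurement tables, where logIE is a known linear function
of nitrogen count, monoisotopic mass and eluent pH plus Gaussian noise;
(3) MS2 spectral libraries whose fragments are the precursor minus
planted neutral losses tied deterministically to the structure (water
always; ammonia for amines; CO2 and formic acid for carboxylic acids;
ethylene for longer chains; acetylene for aromatics; formaldehyde for
hydroxyls), with mass jitter and Poisson noise fragments.

Fragments come from planted losses, not from chemically plausible bond
cleavages — enough to exercise every CNL stage; fragmentation realism is
a non-goal. Records violating the spectral quality filters (negative
mode, low resolution, missing InChIKey, wrong adduct) are injected at
configurable known rates so filter tallies have exact expectations.
All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .compounds import CompoundRecord, IEMeasurement
from .spectra import PROTON_MASS, Spectrum

__all__ = [
    "SimulationConfig",
    "SimulatedCompound",
    "SimulatedSpectra",
    "simulate_compounds",
    "simulate_ie",
    "simulate_spectra",
    "simulate_suspect_hits",
]

# planted neutral losses (Da) keyed by the structural trigger
PLANTED_LOSSES = {
    "water": 18.010565,
    "ammonia": 17.026549,
    "double_ammonia": 34.053098,
    "co2": 43.989830,
    "formic_acid": 46.005480,
    "ethylene": 28.031300,
    "acetylene": 26.015650,
    "formaldehyde": 30.010565,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    ``ie_coefficients`` are the planted weights of the logIE formula
    logIE = intercept + nitrogen*n_N + mass*(M/1000) + ph*pH; with the
    defaults the pH term carries the largest variance and is therefore
    the planted dominant feature.
    """

    seed: int
    n_compounds: int = 50
    spectra_per_compound: int = 4
    ph_levels_per_compound: int = 2
    measurements_per_level: int = 2
    ph_range: tuple[float, float] = (2.0, 10.0)
    ph_jitter: float = 0.3
    ie_coefficients: dict = field(
        default_factory=lambda: {
            "intercept": -1.0,
            "nitrogen": 0.5,
            "mass": 2.0,
            "ph": 0.3,
        }
    )
    ie_noise_sd: float = 0.1
    loss_presence_prob: float = 1.0
    mass_jitter_sd: float = 0.003  # Th
    noise_fragment_rate: float = 1.0  # Poisson mean per spectrum
    resolution: float = 17500.0
    # injection rates for filter-violating records (fraction of clean count)
    negative_mode_rate: float = 0.0
    low_resolution_rate: float = 0.0
    missing_inchikey_rate: float = 0.0
    wrong_adduct_rate: float = 0.0


@dataclass(frozen=True)
class SimulatedCompound:
    record: CompoundRecord
    chain_len: int
    n_amine: int
    n_acid: int
    n_hydroxyl: int
    aromatic: bool
    branch: bool
    n_nitrogen: int
    n_oxygen: int
    monoisotopic_mass: float

    @property
    def planted_losses(self) -> dict[str, float]:
        losses = {"water": PLANTED_LOSSES["water"]}
        if self.n_amine >= 1:
            losses["ammonia"] = PLANTED_LOSSES["ammonia"]
        if self.n_amine >= 2:
            losses["double_ammonia"] = PLANTED_LOSSES["double_ammonia"]
        if self.n_acid >= 1:
            losses["co2"] = PLANTED_LOSSES["co2"]
            losses["formic_acid"] = PLANTED_LOSSES["formic_acid"]
        if self.chain_len >= 3:
            losses["ethylene"] = PLANTED_LOSSES["ethylene"]
        if self.aromatic:
            losses["acetylene"] = PLANTED_LOSSES["acetylene"]
        if self.n_hydroxyl >= 1:
            losses["formaldehyde"] = PLANTED_LOSSES["formaldehyde"]
        return losses

    def planted_log_ie(self, ph: float, coeffs: dict) -> float:
        return (
            coeffs["intercept"]
            + coeffs["nitrogen"] * self.n_nitrogen
            + coeffs["mass"] * self.monoisotopic_mass / 1000.0
            + coeffs["ph"] * ph
        )


def _assemble_smiles(
    chain_len: int,
    n_amine: int,
    n_acid: int,
    n_hydroxyl: int,
    aromatic: bool,
    branch: bool,
) -> str | None:
    """Combinatorial SMILES; None when the decorations do not fit."""
    decorations = []
    if n_amine >= 2:
        decorations.append("(CN)")
    if branch:
        decorations.append("(C)")
    decorations += ["(O)"] * n_hydroxyl
    if n_acid >= 2:
        decorations.append("(C(=O)O)")
    if len(decorations) > chain_len:
        return None
    tokens = [
        "C" + (decorations[i] if i < len(decorations) else "")
        for i in range(chain_len)
    ]
    return (
        ("N" if n_amine >= 1 else "")
        + "".join(tokens)
        + ("c1ccccc1" if aromatic else "")
        + ("C(=O)O" if n_acid >= 1 else "")
    )


def simulate_compounds(config: SimulationConfig) -> list[SimulatedCompound]:
    """Draw ``n_compounds`` distinct valid structures from the template grid."""
    grid = [
        (length, na, nac, noh, ar, br)
        for length in range(1, 16)
        for na in range(3)
        for nac in range(3)
        for noh in range(3)
        for ar in (False, True)
        for br in (False, True)
    ]
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(grid))
    out: list[SimulatedCompound] = []
    seen: set[str] = set()
    for idx in order:
        length, na, nac, noh, ar, br = grid[idx]
        smiles = _assemble_smiles(length, na, nac, noh, ar, br)
        if smiles is None:
            continue
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        inchikey = Chem.MolToInchiKey(mol)
        if not inchikey or inchikey in seen:
            continue
        seen.add(inchikey)
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        out.append(
            SimulatedCompound(
                record=CompoundRecord(
                    inchikey=inchikey, smiles=Chem.MolToSmiles(mol)
                ),
                chain_len=length,
                n_amine=na,
                n_acid=nac,
                n_hydroxyl=noh,
                aromatic=ar,
                branch=br,
                n_nitrogen=symbols.count("N"),
                n_oxygen=symbols.count("O"),
                monoisotopic_mass=Descriptors.ExactMolWt(mol),
            )
        )
        if len(out) == config.n_compounds:
            return out
    raise ValueError(
        f"template grid yields only {len(out)} distinct compounds; "
        f"requested {config.n_compounds}"
    )


def simulate_ie(
    compounds: Sequence[SimulatedCompound], config: SimulationConfig
) -> list[IEMeasurement]:
    """IE measurement table with the planted logIE formula plus noise.

    Each compound is measured at ``ph_levels_per_compound`` distinct
    whole-number pH levels with ``measurements_per_level`` replicates at
    jittered pH, exercising the pH-rounding aggregation.
    """
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.ph_range
    out = []
    for c in compounds:
        levels = rng.choice(
            np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1),
            size=min(
                config.ph_levels_per_compound,
                int(np.floor(hi)) - int(np.ceil(lo)) + 1,
            ),
            replace=False,
        )
        for level in levels:
            for _ in range(config.measurements_per_level):
                ph = float(
                    np.clip(
                        level + rng.uniform(-config.ph_jitter, config.ph_jitter),
                        lo,
                        hi,
                    )
                )
                log_ie = c.planted_log_ie(ph, config.ie_coefficients)
                if config.ie_noise_sd > 0:
                    log_ie += rng.normal(0.0, config.ie_noise_sd)
                out.append(IEMeasurement(c.record, log_ie, ph))
    return out


@dataclass(frozen=True)
class SimulatedSpectra:
    spectra: list[Spectrum]
    truth: pd.DataFrame  # per-spectrum: source_id, inchikey, planted losses
    injected_counts: dict[str, int]


def _clean_spectrum(
    c: SimulatedCompound, rng: np.random.Generator, config: SimulationConfig, i: int
) -> tuple[Spectrum, list[str]]:
    precursor = c.monoisotopic_mass + PROTON_MASS
    mzs, planted = [], []
    for name, loss in c.planted_losses.items():
        if config.loss_presence_prob < 1.0 and rng.random() > config.loss_presence_prob:
            continue
        jitter = (
            rng.normal(0.0, config.mass_jitter_sd)
            if config.mass_jitter_sd > 0
            else 0.0
        )
        mzs.append(precursor - loss + jitter)
        planted.append(name)
    n_noise = int(rng.poisson(config.noise_fragment_rate))
    for _ in range(n_noise):
        mzs.append(float(rng.uniform(50.0, max(precursor - 5.0, 51.0))))
    peaks = tuple(
        (mz, float(rng.uniform(10.0, 100.0))) for mz in mzs if mz > 0
    )
    spectrum = Spectrum(
        precursor_mz=precursor,
        peaks=peaks,
        adduct="[M+H]+",
        ionization_mode="positive",
        resolution=config.resolution,
        inchikey=c.record.inchikey,
        source_id=f"{c.record.inchikey}|rep{i}",
    )
    return spectrum, planted


def simulate_spectra(
    compounds: Sequence[SimulatedCompound], config: SimulationConfig
) -> SimulatedSpectra:
    """MS2 library with planted CNLs plus filter-violating injections."""
    rng = np.random.default_rng(config.seed + 2)
    spectra: list[Spectrum] = []
    rows = []
    for c in compounds:
        for i in range(config.spectra_per_compound):
            s, planted = _clean_spectrum(c, rng, config, i)
            spectra.append(s)
            rows.append(
                {
                    "source_id": s.source_id,
                    "inchikey": c.record.inchikey,
                    "planted_losses": ";".join(planted),
                    "injected_violation": "",
                }
            )

    n_clean = len(spectra)
    injections = {
        "negative_mode": int(round(config.negative_mode_rate * n_clean)),
        "low_resolution": int(round(config.low_resolution_rate * n_clean)),
        "missing_inchikey": int(round(config.missing_inchikey_rate * n_clean)),
        "wrong_adduct": int(round(config.wrong_adduct_rate * n_clean)),
    }
    donor = 0
    for kind, count in injections.items():
        for _ in range(count):
            base = spectra[donor % n_clean]
            donor += 1
            fields = {
                "precursor_mz": base.precursor_mz,
                "peaks": base.peaks,
                "adduct": base.adduct,
                "ionization_mode": base.ionization_mode,
                "resolution": base.resolution,
                "inchikey": base.inchikey,
                "source_id": f"{base.source_id}|inj:{kind}",
            }
            if kind == "negative_mode":
                fields["ionization_mode"] = "negative"
            elif kind == "low_resolution":
                fields["resolution"] = 1000.0
            elif kind == "missing_inchikey":
                fields["inchikey"] = None
            elif kind == "wrong_adduct":
                fields["adduct"] = "[M+Na]+"
            s = Spectrum(**fields)
            spectra.append(s)
            rows.append(
                {
                    "source_id": s.source_id,
                    "inchikey": s.inchikey or "",
                    "planted_losses": "",
                    "injected_violation": kind,
                }
            )
    return SimulatedSpectra(
        spectra=spectra, truth=pd.DataFrame(rows), injected_counts=injections
    )


def simulate_suspect_hits(
    compounds: Sequence[SimulatedCompound], config: SimulationConfig
) -> pd.DataFrame:
    """Suspect-screening hit table: InChIKey, feature mass, fragment m/z."""
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    for c in compounds:
        s, _ = _clean_spectrum(c, rng, config, 0)
        rows.append(
            {
                "inchikey": c.record.inchikey,
                "feature_mass": s.precursor_mz,
                "fragments": ";".join(f"{p[0]:.4f}" for p in s.peaks),
            }
        )
    return pd.DataFrame(rows)
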