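"""CNL vocabulary, binary encoding, consensus spectra, feature assembly.

The structure-free logIE model does not see fragments directly: each
spectrum is reduced to its cumulative neutral losses (CNLs), the losses
observed across the whole library are ranked by how many spectra contain
them, and the most frequent values (default 400, counted in 0.01 Th
bins) form a fixed vocabulary. A spectrum is then a binary vector over
that vocabulary — a bit is set when any of the spectrum's losses falls
within +/-20 mDa of the bin value — prefixed by the precursor
monoisotopic mass scaled by 1000 and the eluent pH scaled by 14.

Consensus filtering removes improbable fragments on the training side:
losses of all spectra of one compound are grouped at 20 mDa tolerance,
groups present in at least a fraction S_min of the spectra form the
consensus, and each spectrum is either replaced by the consensus
("replace") or intersected with it ("filter"). Spectra left with fewer
than CNL_min losses are discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .spectra import CNLSet

__all__ = [
    "CNLVocabulary",
    "CNLVector",
    "ConsensusConfig",
    "build_vocabulary",
    "encode",
    "build_consensus",
    "apply_consensus",
    "assemble_features",
    "MASS_SCALE",
    "PH_SCALE",
]

MASS_SCALE = 1000.0
PH_SCALE = 14.0
DEFAULT_TOL = 0.020  # Th


@dataclass(frozen=True)
class CNLVocabulary:
    """Retained CNL bins (ascending, 0.01 Th resolution) with counts."""

    bins: tuple[float, ...]
    counts: tuple[int, ...]
    top_k: int
    bin_width: float = 0.01

    def __len__(self) -> int:
        return len(self.bins)

    def feature_names(self) -> list[str]:
        return [f"cnl_{b:.2f}" for b in self.bins]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.bins, "count": self.counts})


@dataclass(frozen=True)
class CNLVector:
    """Binary CNL encoding of one spectrum plus its model covariates."""

    bits: np.ndarray
    precursor_mz: float
    ph: float
    inchikey: str | None = None
    log_ie: float | None = None  # training only


@dataclass(frozen=True)
class ConsensusConfig:
    s_min: float = 0.0
    algorithm: Literal["replace", "filter"] = "filter"
    cnl_min: int = 0

    def __post_init__(self):
        if not 0 <= self.s_min < 1:
            raise ValueError("s_min must be in [0, 1)")
        if self.cnl_min < 0:
            raise ValueError("cnl_min must be >= 0")
        if self.algorithm not in ("replace", "filter"):
            raise ValueError(f"unknown consensus algorithm {self.algorithm!r}")


def build_vocabulary(
    cnl_sets: Sequence[CNLSet], top_k: int = 400, bin_width: float = 0.01
) -> CNLVocabulary:
    """Rank CNL bins by the number of spectra containing them.

    Each spectrum contributes at most one count per bin (presence, not
    multiplicity). Ties in count break toward the smaller bin value. If
    fewer than ``top_k`` distinct bins exist, all are returned.
    """
    if not cnl_sets:
        raise ValueError("no CNL sets to build a vocabulary from")
    counter: Counter[float] = Counter()
    for s in cnl_sets:
        counter.update({round(loss / bin_width) * bin_width for loss in s.losses})
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k > len(ranked):
        import warnings

        warnings.warn(
            f"top_k={top_k} exceeds {len(ranked)} distinct bins; keeping all"
        )
    selected = sorted(ranked[:top_k])
    return CNLVocabulary(
        bins=tuple(b for b, _ in selected),
        counts=tuple(c for _, c in selected),
        top_k=min(top_k, len(ranked)),
        bin_width=bin_width,
    )


def encode(
    spectrum_cnls: CNLSet,
    vocab: CNLVocabulary,
    tol: float = DEFAULT_TOL,
    ph: float = float("nan"),
    log_ie: float | None = None,
) -> CNLVector:
    """Bit j = 1 iff some loss lies within +/- tol of vocabulary bin j."""
    bins = np.asarray(vocab.bins)
    bits = np.zeros(len(bins), dtype=np.int64)
    if spectrum_cnls.losses:
        losses = np.asarray(spectrum_cnls.losses)
        # one loss may set several bins when bins are closer than 2*tol
        bits = (
            (np.abs(bins[:, None] - losses[None, :]) <= tol + 1e-12)
            .any(axis=1)
            .astype(np.int64)
        )
    return CNLVector(
        bits=bits,
        precursor_mz=spectrum_cnls.precursor_mz,
        ph=ph,
        inchikey=spectrum_cnls.inchikey,
        log_ie=log_ie,
    )


def _group_losses(
    cnl_sets: Sequence[CNLSet], tol: float
) -> list[tuple[float, set[int]]]:
    """Single-linkage grouping of all losses across spectra.

    Sorted losses are swept ascending; a gap larger than ``tol`` starts a
    new group. Returns (mean value, set of contributing spectrum indices)
    per group.
    """
    tagged = sorted(
        (loss, i) for i, s in enumerate(cnl_sets) for loss in s.losses
    )
    groups: list[tuple[float, set[int]]] = []
    current: list[tuple[float, int]] = []
    for loss, i in tagged:
        if current and loss - current[-1][0] > tol:
            groups.append(
                (float(np.mean([v for v, _ in current])), {j for _, j in current})
            )
            current = []
        current.append((loss, i))
    if current:
        groups.append(
            (float(np.mean([v for v, _ in current])), {j for _, j in current})
        )
    return groups


def _check_single_compound(cnl_sets: Sequence[CNLSet]) -> str | None:
    keys = {s.inchikey for s in cnl_sets}
    if len(keys) > 1:
        raise ValueError(f"consensus over mixed InChIKeys: {sorted(map(str, keys))}")
    return next(iter(keys))


def build_consensus(
    spectra_of_compound: Sequence[CNLSet],
    s_min: float = 0.0,
    tol: float = DEFAULT_TOL,
) -> CNLSet:
    """Consensus CNL set: loss groups present in >= s_min of the spectra.

    The comparison is inclusive, so ``s_min=0`` keeps every group. Each
    kept group is represented by the mean of its member values.
    """
    if not spectra_of_compound:
        raise ValueError("no spectra for consensus")
    key = _check_single_compound(spectra_of_compound)
    n = len(spectra_of_compound)
    kept = [
        value
        for value, members in _group_losses(spectra_of_compound, tol)
        if len(members) / n >= s_min
    ]
    return CNLSet(
        losses=tuple(sorted(kept)),
        precursor_mz=float(
            np.mean([s.precursor_mz for s in spectra_of_compound])
        ),
        inchikey=key,
    )


def apply_consensus(
    spectra_of_compound: Sequence[CNLSet],
    config: ConsensusConfig,
    tol: float = DEFAULT_TOL,
) -> list[CNLSet]:
    """Apply consensus filtering to all spectra of one compound.

    ``replace``: the compound's spectra collapse to its single consensus
    set (one row, to avoid duplicating training weight). ``filter``: each
    spectrum keeps only losses within ``tol`` of a consensus loss,
    preserving per-spectrum identity. Afterwards, sets with fewer than
    ``cnl_min`` losses are discarded.
    """
    consensus = build_consensus(spectra_of_compound, config.s_min, tol)
    if config.algorithm == "replace":
        result = [consensus]
    else:
        ref = np.asarray(consensus.losses)
        result = []
        for s in spectra_of_compound:
            if ref.size and s.losses:
                losses = np.asarray(s.losses)
                keep = (
                    np.abs(losses[:, None] - ref[None, :]) <= tol + 1e-12
                ).any(axis=1)
                new_losses = tuple(losses[keep].tolist())
            else:
                new_losses = ()
            result.append(
                CNLSet(
                    losses=new_losses,
                    precursor_mz=s.precursor_mz,
                    inchikey=s.inchikey,
                    n_dropped=s.n_dropped,
                )
            )
    return [s for s in result if len(s) >= config.cnl_min]


def assemble_features(vectors: Sequence[CNLVector], vocab: CNLVocabulary) -> pd.DataFrame:
    """Model matrix: [precursor_mz/1000, ph/14, CNL bits...], row-aligned.

    Mass and pH are scaled purely for numerical uniformity across
    features; trees are invariant to it, so it never changes predictions.
    """
    if not vectors:
        raise ValueError("no CNL vectors to assemble")
    n_bits = {len(v.bits) for v in vectors}
    if n_bits != {len(vocab)}:
        raise ValueError(
            f"vector lengths {sorted(n_bits)} do not match vocabulary "
            f"size {len(vocab)} (mixed vocabularies?)"
        )
    X = pd.DataFrame(
        np.vstack([v.bits for v in vectors]), columns=vocab.feature_names()
    )
    X.insert(0, "ph_scaled", [v.ph / PH_SCALE for v in vectors])
    X.insert(0, "precursor_mz_scaled", [v.precursor_mz / MASS_SCALE for v in vectors])
    return X
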