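"""Leverage computation and leverage-stratified train/test splitting.

The leverage of compound i is the i-th diagonal element of the hat
matrix, h_i = x_i (XᵀX)⁻¹ x_iᵀ, where X is the compound-by-feature
fingerprint matrix. Low leverage means the compound sits in a densely
populated region of the fingerprint space; high leverage means it is
structurally unusual. Splitting within leverage strata keeps both
subsets representative of the dataset's structural diversity.

Binary fingerprint matrices are routinely rank-deficient, so XᵀX is
inverted with the Moore-Penrose pseudo-inverse (computed via SVD). The
diagonal then satisfies 0 <= h_i <= 1 and sum(h) = rank(X).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitAssignment", "leverage", "stratified_split"]


def leverage(X) -> np.ndarray:
    """Hat-matrix diagonal h_i = x_i (XᵀX)⁻ x_iᵀ via SVD/pseudo-inverse."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a non-empty 2-D numeric matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    # numpy's default pinv cutoff
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    h = (U[:, s > tol] ** 2).sum(axis=1)
    if h.min(initial=0.0) < -1e-9 or h.max(initial=0.0) > 1 + 1e-9:
        raise AssertionError("leverage outside [0, 1] beyond tolerance")
    return np.clip(h, 0.0, 1.0)


@dataclass(frozen=True)
class SplitAssignment:
    """Per-compound train/test labels from a stratified draw."""

    is_test: np.ndarray  # bool per compound
    stratum: np.ndarray  # int per compound
    leverage: np.ndarray
    seed: int
    n_strata: int
    test_ratio: float

    @property
    def train_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_test)

    @property
    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_test)

    def to_frame(self, keys=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "stratum": self.stratum,
                "leverage": self.leverage,
                "label": np.where(self.is_test, "test", "train"),
            }
        )
        if keys is not None:
            df.insert(0, "inchikey", list(keys))
        return df


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    h: np.ndarray,
    test_ratio: float = 0.2,
    n_strata: int = 10,
    seed: int = 1,
) -> SplitAssignment:
    """Split compounds into train/test within equal-count leverage strata.

    The leverage distribution is divided into ``n_strata`` equal-count
    quantile strata (ties broken by input order); within each stratum a
    seeded uniform draw assigns round(size * test_ratio) compounds to the
    test set, with a deterministic correction pass so the overall test
    count equals round(n * test_ratio).
    """
    h = np.asarray(h, dtype=float)
    n = len(h)
    if not 0 < test_ratio < 1:
        raise ValueError("test_ratio must be in (0, 1)")
    if n_strata < 1 or n_strata > n:
        raise ValueError(f"n_strata must be in [1, {n}]")

    order = np.argsort(h, kind="stable")
    strata_members = np.array_split(order, n_strata)
    stratum = np.empty(n, dtype=int)
    for s, members in enumerate(strata_members):
        stratum[members] = s

    sizes = np.array([len(m) for m in strata_members])
    counts = np.array([_round_half_up(sz * test_ratio) for sz in sizes])
    target = _round_half_up(n * test_ratio)
    remainders = sizes * test_ratio - np.floor(sizes * test_ratio + 0.5)
    # deterministic correction: trim/add where rounding deviated most
    while counts.sum() > target:
        eligible = np.flatnonzero(counts > 0)
        counts[eligible[np.argsort(remainders[eligible], kind="stable")[0]]] -= 1
    while counts.sum() < target:
        eligible = np.flatnonzero(counts < sizes)
        counts[eligible[np.argsort(-remainders[eligible], kind="stable")[0]]] += 1

    rng = np.random.default_rng(seed)
    is_test = np.zeros(n, dtype=bool)
    for members, c in zip(strata_members, counts):
        if c:
            is_test[rng.choice(members, size=c, replace=False)] = True

    return SplitAssignment(
        is_test=is_test,
        stratum=stratum,
        leverage=h,
        seed=seed,
        n_strata=n_strata,
        test_ratio=test_ratio,
    )
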