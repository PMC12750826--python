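"""End-to-end logIE pipelines: structure-based (FP) and spectrum-based (CNL).

These functions wire the modules together exactly as the two workflows
require: IE aggregation, fingerprinting, leverage-stratified 80/20
splitting on unique compounds, train-side-only consensus filtering for
the CNL track, model fitting, and evaluation. The test subset is never
touched by consensus filtering — that kind of noise removal is
impossible for real unknown analytes — and the workflow asserts it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cnl_features as cf
from . import models
from .compounds import IEEntry
from .fingerprints import build_feature_matrix, compute_fingerprint
from .leverage_split import SplitAssignment, leverage, stratified_split
from .spectra import CNLSet, FilterTally, Spectrum, compute_cnls, filter_spectra

__all__ = [
    "FPResult",
    "CNLResult",
    "train_fp_workflow",
    "train_cnl_workflow",
    "predict_fp",
    "predict_cnl",
    "evaluate_suspects",
]


def _unique_compounds(entries: Sequence[IEEntry]) -> list[IEEntry]:
    """First entry per InChIKey, in first-appearance order."""
    seen: dict[str, IEEntry] = {}
    for e in entries:
        seen.setdefault(e.compound.key, e)
    return list(seen.values())


def _compound_split(
    entries: Sequence[IEEntry],
    family: str,
    seed: int,
    test_ratio: float,
    n_strata: int,
) -> tuple[list[str], SplitAssignment, set[str]]:
    """Leverage-stratified split on unique compounds (not entries)."""
    uniques = _unique_compounds(entries)
    keys = [e.compound.key for e in uniques]
    fps = np.vstack(
        [compute_fingerprint(e.compound.smiles, family).bits for e in uniques]
    )
    h = leverage(fps)
    n_strata = min(n_strata, len(keys))
    split = stratified_split(h, test_ratio=test_ratio, n_strata=n_strata, seed=seed)
    test_keys = {keys[i] for i in split.test_indices}
    return keys, split, test_keys


# ---------------------------------------------------------------------------
# FP workflow


@dataclass
class FPResult:
    model: models.TrainedModel
    family: str
    params: dict
    split_frame: pd.DataFrame
    train_report: models.EvaluationReport
    test_report: models.EvaluationReport
    search_trace: list = field(default_factory=list)


def train_fp_workflow(
    entries: Sequence[IEEntry],
    family: str = "pubchem",
    params: Mapping | None = None,
    search_iter: int = 0,
    seed: int = 1,
    test_ratio: float = 0.2,
    n_strata: int = 10,
) -> FPResult:
    """Train the structure-based model on aggregated IE entries."""
    keys, split, test_keys = _compound_split(
        entries, family, seed, test_ratio, n_strata
    )
    X = build_feature_matrix(entries, family)
    y = np.array([e.log_ie for e in entries])
    is_test = np.array([e.compound.key in test_keys for e in entries])

    params = dict(params or models.DEFAULT_FP_PARAMS)
    trace: list = []
    if search_iter:
        params, trace = models.randomized_search(
            models.FP_SEARCH_SPACE, X[~is_test], y[~is_test], search_iter, seed
        )
    model = models.train(X[~is_test], y[~is_test], params)
    model.meta = {"family": family, "seed": seed}
    return FPResult(
        model=model,
        family=family,
        params=params,
        split_frame=split.to_frame(keys),
        train_report=models.evaluate(y[~is_test], models.predict(model, X[~is_test])),
        test_report=models.evaluate(y[is_test], models.predict(model, X[is_test])),
        search_trace=trace,
    )


def predict_fp(
    model: models.TrainedModel, smiles: Sequence[str], ph: float | Sequence[float]
) -> np.ndarray:
    """Predict logIE for SMILES at the given eluent pH."""
    family = model.meta.get("family", "pubchem")
    ph_values = np.broadcast_to(np.asarray(ph, dtype=float), (len(smiles),))
    X = pd.DataFrame(
        np.vstack([compute_fingerprint(s, family).bits for s in smiles]),
        columns=model.feature_names[:-1],
    )
    X["ph"] = ph_values
    return models.predict(model, X)


# ---------------------------------------------------------------------------
# CNL workflow


@dataclass
class CNLResult:
    model: models.TrainedModel
    vocabulary: cf.CNLVocabulary
    params: dict
    filter_tally: FilterTally
    split_frame: pd.DataFrame
    train_report: models.EvaluationReport
    test_report: models.EvaluationReport
    n_train_rows: int
    n_test_rows: int
    search_trace: list = field(default_factory=list)


def _rows_for(
    entries: Sequence[IEEntry],
    sets_by_compound: Mapping[str, Sequence[CNLSet]],
    vocab: cf.CNLVocabulary,
) -> tuple[list[cf.CNLVector], np.ndarray]:
    vectors, targets = [], []
    for e in entries:
        for s in sets_by_compound.get(e.compound.key, ()):
            vectors.append(cf.encode(s, vocab, ph=e.ph, log_ie=e.log_ie))
            targets.append(e.log_ie)
    return vectors, np.array(targets)


def _preprocess_train_sets(
    sets_by_compound: Mapping[str, list[CNLSet]],
    train_keys: set[str],
    config: cf.ConsensusConfig,
) -> dict[str, list[CNLSet]]:
    """Consensus-filter the training side; the test side passes through."""
    out: dict[str, list[CNLSet]] = {}
    for key, sets in sets_by_compound.items():
        if key in train_keys:
            pre = [s for s in sets if len(s) >= config.cnl_min]
            out[key] = cf.apply_consensus(pre, config) if pre else []
        else:
            out[key] = list(sets)
    return out


def train_cnl_workflow(
    entries: Sequence[IEEntry],
    spectra: Sequence[Spectrum],
    family: str = "pubchem",
    params: Mapping | None = None,
    search_iter: int = 0,
    seed: int = 1,
    vocab_size: int = 400,
    test_ratio: float = 0.2,
    n_strata: int = 10,
) -> CNLResult:
    """Train the spectrum-based model.

    Spectra are quality-filtered, reduced to CNL sets and joined to the
    IE entries by InChIKey. The compound-level leverage split uses the
    fingerprint family selected by the structure-based track, so both
    models see the same notion of structural diversity. The consensus
    stage (and its CNL_min re-filter) applies to training compounds
    only; preprocessing hyperparameters are searched jointly with the
    model's by re-running that stage inside the search loop.
    """
    kept, tally = filter_spectra(spectra)
    if not kept:
        raise ValueError("no spectra survive quality filtering")
    sets_by_compound: dict[str, list[CNLSet]] = {}
    for s in kept:
        sets_by_compound.setdefault(s.inchikey, []).append(compute_cnls(s))

    entries = [e for e in entries if e.compound.key in sets_by_compound]
    if not entries:
        raise ValueError("no IE entries with matching spectra")
    vocab = cf.build_vocabulary(
        [c for sets in sets_by_compound.values() for c in sets], top_k=vocab_size
    )

    keys, split, test_keys = _compound_split(
        entries, family, seed, test_ratio, n_strata
    )
    train_keys = set(keys) - test_keys

    params = dict(params or models.DEFAULT_CNL_PARAMS)
    trace: list = []
    train_entries = [e for e in entries if e.compound.key in train_keys]
    test_entries = [e for e in entries if e.compound.key in test_keys]

    def _train_matrix(p: Mapping) -> tuple[pd.DataFrame, np.ndarray]:
        config = cf.ConsensusConfig(
            s_min=float(p.get("s_min", 0.0)),
            algorithm=p.get("consensus_algorithm", "filter"),
            cnl_min=int(p.get("cnl_min", 0)),
        )
        processed = _preprocess_train_sets(sets_by_compound, train_keys, config)
        vectors, y = _rows_for(train_entries, processed, vocab)
        if not vectors:
            raise ValueError("preprocessing removed every training row")
        return cf.assemble_features(vectors, vocab), y

    if search_iter:
        rng = np.random.default_rng(seed)
        best, best_score = None, np.inf
        for _ in range(search_iter):
            cand = models.CNL_SEARCH_SPACE.sample(rng)
            try:
                X_tr, y_tr = _train_matrix(cand)
            except ValueError:
                continue
            _, inner = models.randomized_search(
                models.SearchSpace({k: [v] for k, v in cand.items()
                                    if k in models.DEFAULT_FP_PARAMS}),
                X_tr, y_tr, n_iter=1, seed=seed,
            )
            score = inner[0]["cv_rmse"]
            trace.append({"params": cand, "cv_rmse": score})
            if score < best_score:
                best, best_score = cand, score
        if best is not None:
            params = best

    X_train, y_train = _train_matrix(params)
    model = models.train(X_train, y_train, params)
    model.meta = {"family": family, "seed": seed, "vocab_size": len(vocab)}

    # the test side must reach evaluation untouched by consensus filtering
    test_vectors, y_test = _rows_for(test_entries, sets_by_compound, vocab)
    X_test = cf.assemble_features(test_vectors, vocab) if test_vectors else None

    return CNLResult(
        model=model,
        vocabulary=vocab,
        params=params,
        filter_tally=tally,
        split_frame=split.to_frame(keys),
        train_report=models.evaluate(y_train, models.predict(model, X_train)),
        test_report=models.evaluate(y_test, models.predict(model, X_test))
        if X_test is not None and len(y_test) >= 2
        else models.EvaluationReport(float("nan"), float("nan"), float("nan"),
                                     np.array([]), 0),
        n_train_rows=len(y_train),
        n_test_rows=len(y_test),
        search_trace=trace,
    )


def predict_cnl(
    model: models.TrainedModel,
    vocab: cf.CNLVocabulary,
    precursor_mz: float,
    fragment_mzs: Sequence[float],
    ph: float,
) -> float:
    """Predict logIE for one feature from its precursor and fragments."""
    losses = tuple(
        sorted(max(precursor_mz - mz, 0.0) for mz in fragment_mzs
               if mz <= precursor_mz + cf.DEFAULT_TOL)
    )
    vec = cf.encode(CNLSet(losses, precursor_mz), vocab, ph=ph)
    X = cf.assemble_features([vec], vocab)
    return float(models.predict(model, X)[0])


def evaluate_suspects(
    hits: pd.DataFrame,
    fp_model: models.TrainedModel,
    cnl_model: models.TrainedModel,
    vocab: cf.CNLVocabulary,
    smiles_by_inchikey: Mapping[str, str],
    ph: float = 2.0,
    min_fragments: int = 3,
) -> dict:
    """Compare FP- and CNL-model predictions on suspect-screening hits.

    ``hits`` columns: inchikey, feature_mass, fragments (';'-separated
    m/z). Hits with fewer than ``min_fragments`` fragments are flagged
    (and excluded from the summary); the FP model needs a SMILES per
    InChIKey, supplied via ``smiles_by_inchikey``.
    """
    required = {"inchikey", "feature_mass", "fragments"}
    if missing := required - set(hits.columns):
        raise ValueError(f"hit table missing columns {sorted(missing)}")
    rows, flagged = [], 0
    for _, row in hits.iterrows():
        frags = [float(x) for x in str(row["fragments"]).split(";") if x]
        if len(frags) < min_fragments:
            flagged += 1
            continue
        smiles = smiles_by_inchikey.get(row["inchikey"])
        if smiles is None:
            continue
        rows.append((smiles, float(row["feature_mass"]), frags))
    if not rows:
        raise ValueError("no usable suspect hits")
    fp_preds = predict_fp(fp_model, [r[0] for r in rows], ph)
    cnl_preds = np.array(
        [predict_cnl(cnl_model, vocab, mass, frags, ph) for _, mass, frags in rows]
    )
    summary = models.compare_fp_cnl(fp_preds, cnl_preds)
    summary["n_used"] = len(rows)
    summary["n_flagged_few_fragments"] = flagged
    return summary
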