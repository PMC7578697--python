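"""Exhaustive channel-subset evaluation for the HC-vs-CL classifier.

Every non-empty subset of a channel grouping -- the eight right-hemisphere
channels CH1-CH8 (255 subsets), the eight left-hemisphere channels
CH9-CH16 (255), or all sixteen (65,535) -- is scored by repeated
stratified 5-fold cross-validation of the linear SVM restricted to those
channels.  All subsets share the same seeded fold partitions, so their
mean MCCs are directly comparable, and results are ranked by mean MCC
(ties: higher mean bACC, then smaller subset, then lexicographic order).

The full bilateral enumeration is 65,535 x 100 SVM fits; a
``max_subset_size`` cap bounds the enumeration for desk-scale runs while
still containing any plausible best subset (the reported best subsets
have at most seven channels).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _solver
from .preprocess import CHANNELS, FeatureTable
from .svm import CVConfig, LinearModel, fold_assignments, train_linear_svm

__all__ = [
    "GROUPINGS",
    "SubsetResult",
    "SearchReport",
    "enumerate_subsets",
    "evaluate_subset",
    "exhaustive_search",
    "top_k",
    "weight_sign_matrix",
]

GROUPINGS: dict[str, tuple[str, ...]] = {
    "right": CHANNELS[:8],
    "left": CHANNELS[8:],
    "bilateral": CHANNELS,
}


@dataclass(frozen=True)
class SubsetResult:
    subset: tuple[str, ...]
    mean_mcc: float
    mean_bacc: float  # fraction in [0, 1]

    @property
    def mean_bacc_pct(self) -> float:
        return 100.0 * self.mean_bacc


@dataclass
class SearchReport:
    grouping: str
    results: list[SubsetResult]  # ranked, best first
    cv: CVConfig
    C: float
    max_subset_size: int | None = None

    def __len__(self) -> int:
        return len(self.results)

    @property
    def best(self) -> SubsetResult:
        return self.results[0]

    def to_json(self, path) -> None:
        payload = {
            "grouping": self.grouping,
            "C": self.C,
            "cv": {"folds": self.cv.folds, "repeats": self.cv.repeats,
                   "stratified": self.cv.stratified, "grouped": self.cv.grouped,
                   "seed": self.cv.seed},
            "max_subset_size": self.max_subset_size,
            "results": [
                {"subset": list(r.subset), "mean_mcc": r.mean_mcc,
                 "mean_bacc_pct": r.mean_bacc_pct}
                for r in self.results
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _grouping_channels(grouping: str) -> tuple[str, ...]:
    try:
        return GROUPINGS[grouping]
    except KeyError:
        raise ValueError(
            f"unknown grouping {grouping!r}; expected one of {tuple(GROUPINGS)}"
        ) from None


def enumerate_subsets(
    grouping: str, max_size: int | None = None
) -> list[tuple[str, ...]]:
    """All non-empty channel subsets, by size then lexicographic order.

    Without a size cap an n-channel grouping yields 2^n - 1 subsets.
    """
    chans = _grouping_channels(grouping)
    top = len(chans) if max_size is None else min(max_size, len(chans))
    return [
        combo
        for size in range(1, top + 1)
        for combo in itertools.combinations(chans, size)
    ]


def _engine_inputs(table: FeatureTable, cfg: CVConfig):
    X = table.X()
    y = table.y.astype(float)
    if np.unique(y).size < 2:
        raise ValueError("feature table must contain both classes")
    grams = _solver.channel_grams(X)
    groups = table.subjects if cfg.grouped else None
    fold_ids = fold_assignments(y, cfg, groups)
    return grams, y, fold_ids


def _pack_subsets(subsets: list[tuple[str, ...]]) -> tuple[np.ndarray, np.ndarray]:
    kmax = max(len(s) for s in subsets)
    packed = np.full((len(subsets), kmax), -1, dtype=np.int64)
    sizes = np.empty(len(subsets), dtype=np.int64)
    for i, s in enumerate(subsets):
        idx = [CHANNELS.index(c) for c in s]
        packed[i, : len(idx)] = idx
        sizes[i] = len(idx)
    return packed, sizes


def evaluate_subset(
    table: FeatureTable,
    subset: tuple[str, ...],
    cfg: CVConfig,
    C: float = 1.0,
) -> SubsetResult:
    """Cross-validated mean MCC/bACC of the SVM on one channel subset."""
    if not subset:
        raise ValueError("subset must be non-empty")
    unknown = set(subset) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    subset = tuple(sorted(set(subset), key=CHANNELS.index))
    grams, y, fold_ids = _engine_inputs(table, cfg)
    packed, sizes = _pack_subsets([subset])
    mcc, bacc = _solver._search_engine(
        grams, y, packed, sizes, fold_ids, cfg.folds, float(C),
        _solver.ENGINE_TOL, _solver.MAX_ITER,
    )
    return SubsetResult(subset=subset, mean_mcc=float(mcc[0]), mean_bacc=float(bacc[0]))


def _rank_key(subset, mcc, bacc):
    return (-mcc, -bacc, len(subset), subset)


def exhaustive_search(
    table: FeatureTable,
    grouping: str,
    cfg: CVConfig,
    C: float = 1.0,
    max_subset_size: int | None = None,
) -> SearchReport:
    """Evaluate every subset of the grouping on shared fold partitions."""
    subsets = enumerate_subsets(grouping, max_subset_size)
    grams, y, fold_ids = _engine_inputs(table, cfg)
    if np.unique(y).size < 2:
        raise ValueError("feature table must contain both classes")
    packed, sizes = _pack_subsets(subsets)
    mcc, bacc = _solver._search_engine(
        grams, y, packed, sizes, fold_ids, cfg.folds, float(C),
        _solver.ENGINE_TOL, _solver.MAX_ITER,
    )
    order = sorted(
        range(len(subsets)),
        key=lambda i: _rank_key(subsets[i], mcc[i], bacc[i]),
    )
    results = [
        SubsetResult(subset=subsets[i], mean_mcc=float(mcc[i]),
                     mean_bacc=float(bacc[i]))
        for i in order
    ]
    return SearchReport(grouping=grouping, results=results, cv=cfg, C=C,
                        max_subset_size=max_subset_size)


def top_k(report: SearchReport, k: int = 5) -> pd.DataFrame:
    """Best-k rows of a ranked report (hemisphere, subset, MCC, bACC %)."""
    if k > len(report):
        warnings.warn(
            f"requested top {k} of a {len(report)}-subset report; truncating"
        )
        k = len(report)
    rows = [
        {
            "hemisphere": report.grouping,
            "subset": ",".join(c.removeprefix("CH") for c in r.subset),
            "MCC": r.mean_mcc,
            "bACC": r.mean_bacc_pct,
        }
        for r in report.results[:k]
    ]
    return pd.DataFrame(rows)


def weight_sign_matrix(
    table: FeatureTable,
    report: SearchReport,
    m: int = 50,
) -> pd.DataFrame:
    """Signed SVM weights of the top-m subsets, refit on the full table.

    One row per subset (rank order), one column per channel in the
    grouping; cells are NaN exactly where the channel is absent from the
    subset.  With CL encoded +1, a positive weight marks a channel whose
    HbO2 runs higher in patients.
    """
    if m > len(report):
        raise ValueError(f"m={m} exceeds report length {len(report)}")
    chans = _grouping_channels(report.grouping)
    y = table.y.astype(float)
    rows = []
    index = []
    for rank, res in enumerate(report.results[:m], start=1):
        X = table.X(res.subset)
        try:
            model: LinearModel = train_linear_svm(X, y, C=report.C)
        except Exception as exc:  # refit failure is flagged, not dropped
            warnings.warn(f"refit failed for subset {res.subset}: {exc}")
            rows.append({c: np.nan for c in chans})
            index.append(rank)
            continue
        row = {c: np.nan for c in chans}
        for c, w in zip(res.subset, model.w):
            row[c] = w
        rows.append(row)
        index.append(rank)
    out = pd.DataFrame(rows, index=pd.Index(index, name="rank"))
    out.insert(0, "subset", [",".join(r.subset) for r in report.results[:m]])
    out.insert(1, "mean_mcc", [r.mean_mcc for r in report.results[:m]])
    return out
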