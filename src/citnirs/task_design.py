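"""Melodic contour identification task (CIT) design and behavioural scoring.

The stimulus space is symbolic: a test item is an ordered pair of two
distinct melodic contour directions (ascending / stationary / descending),
rendered in one of five major keys and one of three instrument timbres.
Each contour lasts 2,250 ms with a 750 ms inter-contour gap, so an item
runs 5,250 ms.  Three task blocks increase the attentional load:

* CIT1 -- target contours against environmental-sound distractors,
* CIT2 -- target contours against target-like contours in another timbre,
* CIT3 -- as CIT2, but attention must shift between contours mid-item,
  guided by a per-contour visual cue.

The module also scores trial-level responses into per-subject accuracy
and reaction-time rows and correlates them with neurocognitive test
scores (number connection tests NCT-A/B, digit span forward/backward).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DIRECTIONS",
    "KEYS",
    "TIMBRES",
    "ENVIRONMENTAL_SOUNDS",
    "CONTOUR_MS",
    "GAP_MS",
    "TestItem",
    "Trial",
    "CitBlock",
    "enumerate_contour_pairs",
    "build_item_pool",
    "build_cit_block",
    "score_behavior",
    "correlate_behavior",
    "pool_to_frame",
    "block_to_frame",
]

DIRECTIONS = ("ascending", "stationary", "descending")
# "G# to C major" spans the chromatic steps G#, A, A#, B, C
KEYS = ("G#", "A", "A#", "B", "C")
TIMBRES = ("piano", "flute", "string")
ENVIRONMENTAL_SOUNDS = (
    "traffic", "raining", "twittering", "ticktack", "bustling",
    "laughing", "gabbling", "applause", "crying", "jeering",
)
CONTOUR_MS = 2250
GAP_MS = 750
CIT_IDS = ("CIT1", "CIT2", "CIT3")

NEUROCOGNITIVE_TESTS = ("NCT-A", "NCT-B", "DST-Forward", "DST-Backward")


@dataclass(frozen=True)
class TestItem:
    """One stimulus: two distinct contour directions in a key and timbre."""

    pair: tuple[str, str]
    key: str
    timbre: str
    contour_ms: int = CONTOUR_MS
    gap_ms: int = GAP_MS

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError("contour pair must combine two distinct directions")
        for d in self.pair:
            if d not in DIRECTIONS:
                raise ValueError(f"unknown contour direction {d!r}")

    @property
    def duration_ms(self) -> int:
        return 2 * self.contour_ms + self.gap_ms


@dataclass(frozen=True)
class Trial:
    item: TestItem
    distractor: str
    visual_cue: str | None


@dataclass(frozen=True)
class CitBlock:
    cit_id: str
    trials: tuple[Trial, ...]

    @property
    def n_items(self) -> int:
        return len(self.trials)


def enumerate_contour_pairs() -> list[tuple[str, str]]:
    """All ordered pairs of distinct directions.

    Canonical order: ``itertools.permutations`` over
    (ascending, stationary, descending) -- 3 x 2 = 6 pairs.
    """
    return list(itertools.permutations(DIRECTIONS, 2))


def build_item_pool(
    keys: tuple[str, ...] = KEYS, timbres: tuple[str, ...] = TIMBRES
) -> list[TestItem]:
    """Cartesian product pairs x keys x timbres (6 x 5 x 3 = 90 by default)."""
    if not keys or not timbres:
        raise ValueError("keys and timbres must be non-empty")
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate keys")
    if len(set(timbres)) != len(timbres):
        raise ValueError("duplicate timbres")
    return [
        TestItem(pair=pair, key=key, timbre=timbre)
        for pair in enumerate_contour_pairs()
        for key in keys
        for timbre in timbres
    ]


def _random_pair(rng: np.random.Generator) -> tuple[str, str]:
    pairs = enumerate_contour_pairs()
    return pairs[rng.integers(len(pairs))]


def build_cit_block(
    cit_id: str,
    pool: list[TestItem],
    n_items: int = 18,
    seed: int = 0,
) -> CitBlock:
    """Draw ``n_items`` trials without replacement and attach distractors.

    CIT1 trials carry an environmental-sound label; CIT2/CIT3 trials a
    target-like contour in a different timbre, plus the visual cue naming
    the target timbre.  CIT3 additionally randomizes which line (upper or
    lower) is attended first.  The same (seed, inputs) reproduce the block.
    """
    if cit_id not in CIT_IDS:
        raise ValueError(f"unknown cit_id {cit_id!r}; expected one of {CIT_IDS}")
    if n_items > len(pool):
        raise ValueError(f"cannot draw {n_items} items from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=n_items, replace=False)]
    trials = []
    for item in chosen:
        if cit_id == "CIT1":
            distractor = ENVIRONMENTAL_SOUNDS[rng.integers(len(ENVIRONMENTAL_SOUNDS))]
            cue = None
        else:
            other_timbres = [t for t in TIMBRES if t != item.timbre]
            d_pair = _random_pair(rng)
            d_timbre = other_timbres[rng.integers(len(other_timbres))]
            distractor = f"{d_pair[0]}+{d_pair[1]}:{d_timbre}"
            cue = f"target:{item.timbre}"
            if cit_id == "CIT3":
                first = "upper" if rng.integers(2) else "lower"
                cue = f"{cue};shift-first:{first}"
        trials.append(Trial(item=item, distractor=distractor, visual_cue=cue))
    return CitBlock(cit_id=cit_id, trials=tuple(trials))


def pool_to_frame(pool: list[TestItem]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "item_id": range(len(pool)),
            "dir1": [it.pair[0] for it in pool],
            "dir2": [it.pair[1] for it in pool],
            "key": [it.key for it in pool],
            "timbre": [it.timbre for it in pool],
            "duration_ms": [it.duration_ms for it in pool],
        }
    )


def block_to_frame(block: CitBlock) -> pd.DataFrame:
    rows = []
    for i, tr in enumerate(block.trials):
        rows.append(
            {
                "cit_id": block.cit_id,
                "trial": i,
                "dir1": tr.item.pair[0],
                "dir2": tr.item.pair[1],
                "key": tr.item.key,
                "timbre": tr.item.timbre,
                "duration_ms": tr.item.duration_ms,
                "distractor": tr.distractor,
                "visual_cue": "" if tr.visual_cue is None else tr.visual_cue,
            }
        )
    return pd.DataFrame(rows)


def score_behavior(responses: pd.DataFrame) -> pd.DataFrame:
    """Aggregate trial-level responses to one row per subject x CIT.

    ``responses`` needs columns subject_id, group, cit_id, correct (bool),
    rt_ms (> 0).  Accuracy is the fraction correct; reaction time the mean
    over answered trials.  A subject x CIT with no responses is reported
    with NaN entries and a warning rather than a silent zero.
    """
    required = {"subject_id", "group", "cit_id", "correct", "rt_ms"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"responses missing columns: {sorted(missing)}")
    if (responses["rt_ms"].dropna() <= 0).any():
        raise ValueError("reaction times must be positive")
    rows = []
    for (sid, grp, cit), sub in responses.groupby(
        ["subject_id", "group", "cit_id"], sort=True
    ):
        answered = sub.dropna(subset=["correct"])
        if len(answered) == 0:
            warnings.warn(f"no responses for subject {sid} {cit}; row flagged missing")
            acc, rt = np.nan, np.nan
        else:
            acc = float(answered["correct"].astype(bool).mean())
            rt = float(answered["rt_ms"].mean())
        rows.append(
            {"subject_id": sid, "group": grp, "cit_id": cit, "accuracy": acc,
             "rt_ms": rt}
        )
    return pd.DataFrame(rows)


def correlate_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (+ two-sided p) between CIT measures and cognitive tests.

    One row per (group, cit, measure, test) cell, ``cit`` including a
    per-subject "Total" average.  Requires >= 3 complete rows per group;
    a zero-variance column makes r undefined: the cell is NaN and a
    warning is emitted.
    """
    tests = [t for t in NEUROCOGNITIVE_TESTS if t in table.columns]
    if not tests:
        raise ValueError("behavior table has no neurocognitive test columns")
    out = []
    for group, gtab in table.groupby("group", sort=True):
        if gtab["subject_id"].nunique() < 3:
            raise ValueError(f"need >= 3 subjects per group, group {group!r} has fewer")
        per_subj = gtab.groupby("subject_id").agg(
            {**{"accuracy": "mean", "rt_ms": "mean"}, **{t: "first" for t in tests}}
        )
        frames = {"Total": per_subj}
        for cit, ctab in gtab.groupby("cit_id", sort=True):
            frames[cit] = ctab.set_index("subject_id")
        for cit, frame in frames.items():
            for measure in ("accuracy", "rt_ms"):
                for test in tests:
                    sub = frame[[measure, test]].dropna()
                    x = sub[measure].to_numpy(float)
                    yv = sub[test].to_numpy(float)
                    if len(sub) < 3 or np.std(x) == 0.0 or np.std(yv) == 0.0:
                        warnings.warn(
                            f"correlation undefined for {group}/{cit}/{measure}/{test}"
                        )
                        r = p = np.nan
                    else:
                        r, p = stats.pearsonr(x, yv)
                    out.append(
                        {"group": group, "cit": cit, "measure": measure,
                         "test": test, "r": float(r), "p": float(p), "n": len(sub)}
                    )
    return pd.DataFrame(out)
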