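"""Combinatorial-pharmacophore model enumeration, scoring and selection.

A CP model is an unordered set of hypotheses classifying by the union rule: a
ligand is predicted active iff it matches at least one member.  All 3- and
4-member subsets of the retained hypothesis pool are enumerated (C(n,3) +
C(n,4) candidates) and the one with the highest balanced accuracy on the
calibration set is selected.  Because inhibitor screens are heavily skewed
towards inactives, BACC = (SE + SP) / 2 rather than raw accuracy drives
selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

STANDARD_SIZES = (3, 4)


@dataclass
class ConfusionMetrics:
    """Counts plus SE, SP, ACC and BACC derived from them."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def se(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def bacc(self) -> float:
        return (self.se + self.sp) / 2

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Report-style rounding; stored values stay at full precision."""
        return {m: round(getattr(self, m), ndigits) for m in ("se", "sp", "acc", "bacc")}

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "se": self.se, "sp": self.sp, "acc": self.acc, "bacc": self.bacc,
        }


@dataclass
class CPModel:
    """An unordered set of member hypotheses classifying by OR."""

    members: frozenset[str]
    metrics_calibration: Optional[ConfusionMetrics] = None
    metrics_test: Optional[ConfusionMetrics] = None

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError("CP model must have at least one member")
        if not set(STANDARD_SIZES) & {len(self.members)} and len(self.members) > max(STANDARD_SIZES):
            raise ValueError("CP model may have at most 4 members")

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))

    def to_dict(self) -> dict:
        d = {"members": list(self.member_ids)}
        if self.metrics_calibration is not None:
            d["metrics_calibration"] = self.metrics_calibration.to_dict()
        if self.metrics_test is not None:
            d["metrics_test"] = self.metrics_test.to_dict()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CPModel":
        d = json.loads(Path(path).read_text())
        model = cls(members=frozenset(d["members"]))
        for attr in ("metrics_calibration", "metrics_test"):
            if attr in d:
                m = d[attr]
                setattr(model, attr, ConfusionMetrics(tp=m["tp"], tn=m["tn"], fp=m["fp"], fn=m["fn"]))
        return model


def classify(record_matches: Sequence[bool]) -> str:
    """Union rule: active iff the ligand matches any member hypothesis."""
    matches = list(record_matches)
    if not matches:
        raise ValueError("empty match vector")
    return "active" if any(matches) else "inactive"


def confusion_metrics(predictions: Sequence[str], truth: Sequence[str]) -> ConfusionMetrics:
    """Confusion counts and SE/SP/ACC/BACC from parallel label sequences."""
    predictions, truth = list(predictions), list(truth)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    for cls in ("active", "inactive"):
        if cls not in truth:
            raise ValueError(f"truth contains no {cls!r} examples")
    tp = sum(1 for p, t in zip(predictions, truth) if p == "active" and t == "active")
    tn = sum(1 for p, t in zip(predictions, truth) if p == "inactive" and t == "inactive")
    fp = sum(1 for p, t in zip(predictions, truth) if p == "active" and t == "inactive")
    fn = sum(1 for p, t in zip(predictions, truth) if p == "inactive" and t == "active")
    return ConfusionMetrics(tp=tp, tn=tn, fp=fp, fn=fn)


def enumerate_cp_models(hyp_pool: Sequence[str], sizes: Sequence[int] = STANDARD_SIZES) -> list[CPModel]:
    """Every unordered subset of each requested size, exactly once.

    Deterministic order: sizes ascending, then lexicographic by sorted member
    ids.  A pool smaller than every requested size yields an empty list with
    a warning.  Count equals sum_s C(len(pool), s).
    """
    pool = sorted(set(hyp_pool))
    if len(pool) != len(list(hyp_pool)):
        raise ValueError("hypothesis pool contains duplicate ids")
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 1 for s in sizes):
        raise ValueError("sizes must be positive")
    feasible = [s for s in sizes if s <= len(pool)]
    if not feasible:
        warnings.warn(f"pool of {len(pool)} smaller than all requested sizes {sizes}")
        return []
    models = []
    for s in feasible:
        for combo in combinations(pool, s):
            models.append(CPModel(members=frozenset(combo)))
    return models


def _truth_vector(match_matrix: pd.DataFrame, truth: pd.Series) -> np.ndarray:
    missing = match_matrix.index.difference(truth.index)
    if len(missing):
        raise ValueError(f"molecules missing from truth labels: {list(missing)}")
    return (truth.reindex(match_matrix.index) == "active").to_numpy()


def _metrics_from_pred(pred: np.ndarray, y: np.ndarray) -> ConfusionMetrics:
    return ConfusionMetrics(
        tp=int(np.sum(pred & y)),
        tn=int(np.sum(~pred & ~y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def evaluate_on_set(model: CPModel, match_matrix: pd.DataFrame, truth: pd.Series) -> ConfusionMetrics:
    """Classify every molecule by the union rule and compute confusion metrics.

    ``truth`` maps mol_id -> {'active', 'inactive'}.  Single hypotheses are
    evaluable as 1-member degenerate models for report tables.
    """
    missing_h = set(model.members) - set(match_matrix.columns)
    if missing_h:
        raise ValueError(f"match matrix missing hypotheses: {sorted(missing_h)}")
    y = _truth_vector(match_matrix, truth)
    pred = match_matrix[list(model.member_ids)].to_numpy(dtype=bool).any(axis=1)
    return _metrics_from_pred(pred, y)


def rank_candidates(candidates: Sequence[CPModel], match_matrix: pd.DataFrame, truth: pd.Series) -> pd.DataFrame:
    """Score every candidate on the calibration set; ranked DataFrame.

    Sorted by (bacc desc, se desc, fewer members, member ids) — the selection
    order used by :func:`select_best`.
    """
    if not candidates:
        raise ValueError("no candidate models supplied")
    y = _truth_vector(match_matrix, truth)
    M = match_matrix.to_numpy(dtype=bool)
    col = {h: i for i, h in enumerate(match_matrix.columns)}
    rows = []
    for cand in candidates:
        idx = [col[h] for h in cand.member_ids]
        pred = M[:, idx].any(axis=1)
        m = _metrics_from_pred(pred, y)
        rows.append(
            {
                "members": "|".join(cand.member_ids),
                "n_members": len(cand.members),
                "tp": m.tp, "tn": m.tn, "fp": m.fp, "fn": m.fn,
                "se": m.se, "sp": m.sp, "acc": m.acc, "bacc": m.bacc,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        by=["bacc", "se", "n_members", "members"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def select_best(candidates: Sequence[CPModel], match_matrix: pd.DataFrame, truth: pd.Series) -> CPModel:
    """The candidate maximising calibration BACC.

    Ties are broken by higher SE (recovering true inhibitors is the stated
    priority), then fewer members, then lexicographic member ids; the result
    is therefore invariant to the candidate order.
    """
    table = rank_candidates(candidates, match_matrix, truth)
    best_row = table.iloc[0]
    members = frozenset(best_row["members"].split("|"))
    model = CPModel(members=members)
    model.metrics_calibration = ConfusionMetrics(
        tp=int(best_row["tp"]), tn=int(best_row["tn"]), fp=int(best_row["fp"]), fn=int(best_row["fn"])
    )
    return model
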