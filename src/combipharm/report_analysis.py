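"""Post-hoc component analyses of a fitted CP model.

Two standard reports: per-hypothesis molecular-weight summaries (which sizes
of ligand each binding-mode hypothesis captures) and class-resolved matching
percentages (which hypotheses discriminate selective from dual inhibitors of
two related transporters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chem_core import MoleculeRecord
from .hypothesis_engine import PharmacophoreHypothesis


@dataclass
class MWSummary:
    """Molecular-weight statistics of the molecules matching one hypothesis."""

    hyp_id: str
    mean: float
    sd: float
    median: float
    min: float
    max: float
    n: int


def mw_by_hypothesis(library: Sequence[MoleculeRecord], match_matrix: pd.DataFrame) -> list[MWSummary]:
    """MW summary per hypothesis over its matching molecules.

    Molecules matching several hypotheses contribute to each summary
    (columns overlap by design); hypotheses matched by nobody are omitted
    with a warning.
    """
    mw = pd.Series({rec.mol_id: rec.mol_weight for rec in library})
    out = []
    for hyp_id in match_matrix.columns:
        matched = match_matrix.index[match_matrix[hyp_id]]
        vals = mw.reindex(matched).dropna().to_numpy()
        if len(vals) == 0:
            warnings.warn(f"hypothesis {hyp_id} matched by no molecule; omitted from MW report")
            continue
        out.append(
            MWSummary(
                hyp_id=hyp_id,
                mean=float(np.mean(vals)),
                sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                median=float(np.median(vals)),
                min=float(np.min(vals)),
                max=float(np.max(vals)),
                n=int(len(vals)),
            )
        )
    return out


def mw_summary_frame(summaries: Sequence[MWSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries]).set_index("hyp_id")


def selectivity_comparison(
    lib_a_selective: Sequence[MoleculeRecord],
    lib_b_selective: Sequence[MoleculeRecord],
    lib_dual: Sequence[MoleculeRecord],
    hyps_a: Sequence[PharmacophoreHypothesis],
    hyps_b: Sequence[PharmacophoreHypothesis],
    matcher: Callable[[MoleculeRecord, PharmacophoreHypothesis], object],
) -> pd.DataFrame:
    """Percentage of each inhibitor class matching each hypothesis.

    Rows are hypotheses (from both transporters' models), columns the three
    classes (A-selective, B-selective, dual).  Percentages are computed per
    class independently and do not sum to 100; an empty class reports NaN.
    Class membership is input metadata, never inferred.
    """
    classes = {
        "A_selective": list(lib_a_selective),
        "B_selective": list(lib_b_selective),
        "dual": list(lib_dual),
    }
    ids = [m.mol_id for lib in classes.values() for m in lib]
    if len(ids) != len(set(ids)):
        raise ValueError("inhibitor classes must be disjoint by mol_id")
    all_hyps = list(hyps_a) + list(hyps_b)
    rows = {}
    for hyp in all_hyps:
        row = {}
        for cname, lib in classes.items():
            if not lib:
                warnings.warn(f"class {cname} is empty; percentage undefined")
                row[cname] = float("nan")
                continue
            n = sum(1 for rec in lib if matcher(rec, hyp).matched)
            row[cname] = 100.0 * n / len(lib)
        rows[hyp.hyp_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def plot_mw_boxplot(library: Sequence[MoleculeRecord], match_matrix: pd.DataFrame, ax=None):
    """Box plot of MW distributions per matched hypothesis (report figure)."""
    import matplotlib.pyplot as plt

    mw = pd.Series({rec.mol_id: rec.mol_weight for rec in library})
    data, labels = [], []
    for hyp_id in match_matrix.columns:
        vals = mw.reindex(match_matrix.index[match_matrix[hyp_id]]).dropna()
        if len(vals):
            data.append(vals.to_numpy())
            labels.append(hyp_id)
    if ax is None:
        _, ax = plt.subplots()
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("Molecular weight (Da)")
    ax.set_xlabel("Hypothesis")
    return ax


def plot_class_matching(percentages: pd.DataFrame, ax=None):
    """Grouped bar chart of class-matching percentages per hypothesis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    percentages.plot.bar(ax=ax)
    ax.set_ylabel("% of class matching")
    ax.set_xlabel("Hypothesis")
    return ax
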