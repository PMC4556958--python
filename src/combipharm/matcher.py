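"""Distance-based matching of feature clouds against pharmacophore hypotheses.

A conformer matches a k-site hypothesis when an injective assignment of its
feature points to the sites exists with site-by-site type agreement and every
pairwise inter-feature distance within ``tol`` of the hypothesis distance.
Matching compares inter-point distances only (no superposition), so it is
rigid-motion invariant by construction and exact for k <= 4.  Among valid
assignments the one minimising the RMS pairwise-distance deviation is
returned, with ties broken by the lexicographically smallest feature-index
tuple.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_core import FeaturePoint, MoleculeRecord
from .hypothesis_engine import PharmacophoreHypothesis

logger = logging.getLogger(__name__)


@dataclass
class MatchResult:
    """Outcome of matching one molecule/conformer against one hypothesis."""

    matched: bool
    conf_id: Optional[int] = None
    assignment: dict[int, FeaturePoint] = field(default_factory=dict)
    max_deviation: float = math.inf
    rmsd_dist: float = math.inf

    def __bool__(self) -> bool:
        return self.matched


def _pair_deviations(idx: Sequence[int], positions: np.ndarray, hyp_dist: np.ndarray) -> tuple[float, float]:
    """(max, rms) deviation of the assigned pairwise distances from the hypothesis."""
    k = len(idx)
    devs = []
    for i in range(k):
        for j in range(i + 1, k):
            d = float(np.linalg.norm(positions[idx[i]] - positions[idx[j]]))
            devs.append(abs(d - hyp_dist[i, j]))
    devs = np.asarray(devs)
    return float(devs.max()), float(np.sqrt(np.mean(devs**2)))


def match_conformer(features: Sequence[FeaturePoint], hyp: PharmacophoreHypothesis, conf_id: Optional[int] = None) -> MatchResult:
    """Exact correspondence search of ``features`` against ``hyp``.

    Backtracking over type-consistent injective site->feature assignments,
    pruning on the per-pair tolerance; complete for k <= 4.  Returns the
    assignment with minimal ``rmsd_dist`` (deterministic tie-break on the
    feature-index tuple), or ``matched=False`` when none exists.
    """
    k = len(hyp.sites)
    positions = np.asarray([fp.xyz for fp in features]) if features else np.empty((0, 3))
    candidates = [
        [i for i, fp in enumerate(features) if fp.ftype == site] for site in hyp.sites
    ]
    if any(not c for c in candidates):
        return MatchResult(matched=False, conf_id=conf_id)

    D = hyp.distance_matrix
    tol = hyp.tol
    best: Optional[tuple[float, tuple[int, ...]]] = None
    assigned: list[int] = []

    def backtrack(site: int) -> None:
        nonlocal best
        if site == k:
            max_dev, rms = _pair_deviations(assigned, positions, D)
            key = (rms, tuple(assigned))
            if best is None or key < best:
                best = key
            return
        for fi in candidates[site]:
            if fi in assigned:
                continue
            ok = True
            for prev_site, prev_fi in enumerate(assigned):
                d = float(np.linalg.norm(positions[fi] - positions[prev_fi]))
                if abs(d - D[site, prev_site]) > tol:
                    ok = False
                    break
            if ok:
                assigned.append(fi)
                backtrack(site + 1)
                assigned.pop()

    backtrack(0)
    if best is None:
        return MatchResult(matched=False, conf_id=conf_id)
    rms, idx = best
    max_dev, _ = _pair_deviations(idx, positions, D)
    return MatchResult(
        matched=True,
        conf_id=conf_id,
        assignment={site: features[fi] for site, fi in enumerate(idx)},
        max_deviation=max_dev,
        rmsd_dist=rms,
    )


def brute_force_match(features: Sequence[FeaturePoint], hyp: PharmacophoreHypothesis) -> MatchResult:
    """Naive full enumeration of all type-consistent assignments (test oracle)."""
    k = len(hyp.sites)
    n = len(features)
    positions = np.asarray([fp.xyz for fp in features]) if features else np.empty((0, 3))
    D = hyp.distance_matrix
    best: Optional[tuple[float, tuple[int, ...]]] = None
    for perm in permutations(range(n), k):
        if any(features[fi].ftype != hyp.sites[s] for s, fi in enumerate(perm)):
            continue
        max_dev, rms = _pair_deviations(perm, positions, D)
        if max_dev <= hyp.tol:
            key = (rms, perm)
            if best is None or key < best:
                best = key
    if best is None:
        return MatchResult(matched=False)
    rms, idx = best
    max_dev, _ = _pair_deviations(idx, positions, D)
    return MatchResult(
        matched=True,
        assignment={s: features[fi] for s, fi in enumerate(idx)},
        max_deviation=max_dev,
        rmsd_dist=rms,
    )


def match_molecule(record: MoleculeRecord, hyp: PharmacophoreHypothesis) -> MatchResult:
    """Best match over the conformer ensemble (any-conformer OR semantics)."""
    if not record.features:
        warnings.warn(f"record {record.mol_id} has no perceived features; treating as non-match")
        return MatchResult(matched=False)
    best = MatchResult(matched=False)
    for conf_id, feats in record.feature_sets():
        res = match_conformer(feats, hyp, conf_id=conf_id)
        if res.matched and (not best.matched or res.rmsd_dist < best.rmsd_dist):
            best = res
    return best


def build_match_matrix(
    library: Sequence[MoleculeRecord],
    hyps: Sequence[PharmacophoreHypothesis],
) -> pd.DataFrame:
    """Boolean molecules x hypotheses match matrix (rows mol_id, columns hyp_id)."""
    data = {
        hyp.hyp_id: [match_molecule(rec, hyp).matched for rec in library] for hyp in hyps
    }
    return pd.DataFrame(data, index=[rec.mol_id for rec in library], dtype=bool)


def write_match_matrix(matrix: pd.DataFrame, path, metadata: Optional[dict] = None) -> None:
    """Persist a match matrix as CSV with '#'-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        matrix.astype(int).to_csv(fh, index_label="mol_id")


def read_match_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col="mol_id")
    df.index = df.index.astype(str)
    return df.astype(bool)
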